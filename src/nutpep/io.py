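"""Readers, writers and shared domain types.

All tabular I/O is tab-delimited UTF-8 with a header row; no CSV
autodetection. Protein input is FASTA with the header convention
``accession|allergen_name|species`` (bare headers are accepted and used
as both accession and name). Scores are rendered with 4 decimal places.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("nutpep")

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / non-standard codes optionally retained in permissive mode.
AMBIGUOUS_RESIDUES = frozenset("BJXZUO")

SCORE_DECIMALS = 4


class NutpepError(Exception):
    """Base class for all package errors."""


class ParseError(NutpepError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(NutpepError):
    """Input violates a domain-type invariant."""


class SchemaError(NutpepError):
    """Tabular input is missing required columns or contains empty fields."""


class DomainError(NutpepError):
    """An operation was called outside its domain of definition."""


def _check_sequence(seq: str, entity: str, allow_ambiguous: bool = False) -> str:
    seq = "".join(seq.split()).upper()
    if not seq:
        raise ValidationError(f"{entity}: empty sequence")
    allowed = STANDARD_RESIDUES | (AMBIGUOUS_RESIDUES if allow_ambiguous else frozenset())
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValidationError(
                f"{entity}: illegal residue {ch!r} at position {pos}"
            )
    return seq


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One allergen chain with its accession and InterPro domain IDs."""

    accession: str
    allergen_name: str = ""
    species: str = ""
    sequence: str = ""
    domain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("ProteinRecord: empty accession")
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, self.accession, True)
        )

    @property
    def n_residues(self) -> int:
        """Chain length N, the denominator of the occurrence/release scores."""
        return len(self.sequence)


@dataclass(frozen=True)
class ActivityEntry:
    peptide: str
    activity: str
    source_id: str | None = None


class ActivityReference:
    """Table of (peptide, activity) pairs defining the bioactive fragments.

    Mirrors a bioactive-peptide database snapshot: mostly di- and
    tripeptides, each annotated with an activity label such as
    "ACE inhibitor". (peptide, activity) pairs are unique.
    """

    def __init__(self, entries: Iterable[ActivityEntry]):
        seen: dict[tuple[str, str], ActivityEntry] = {}
        for e in entries:
            if len(e.peptide) < 1:
                raise ValidationError("ActivityReference: empty peptide")
            if not e.activity:
                raise SchemaError("ActivityReference: empty activity label")
            key = (e.peptide, e.activity)
            if key in seen:
                logger.warning(
                    "duplicate reference row (%s, %s) collapsed", e.peptide, e.activity
                )
                continue
            seen[key] = ActivityEntry(
                _check_sequence(e.peptide, f"peptide {e.peptide!r}"), e.activity, e.source_id
            )
        self.entries: tuple[ActivityEntry, ...] = tuple(seen.values())

    @property
    def activities(self) -> tuple[str, ...]:
        """Distinct activity labels, in first-seen order."""
        out: list[str] = []
        for e in self.entries:
            if e.activity not in out:
                out.append(e.activity)
        return tuple(out)

    def peptides_for(self, activity: str) -> frozenset[str]:
        if activity not in self.activities:
            raise DomainError(f"unknown activity label {activity!r}")
        return frozenset(e.peptide for e in self.entries if e.activity == activity)

    def restricted(self, min_fragment_length: int) -> "ActivityReference":
        """Copy with peptides shorter than ``min_fragment_length`` removed.

        Activity labels whose peptides are all removed stay in the label
        set of the original but vanish here; scores over the restricted
        reference treat them as contributing zero.
        """
        return ActivityReference(
            e for e in self.entries if len(e.peptide) >= min_fragment_length
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ActivityReference) and set(self.entries) == set(other.entries)


@dataclass(frozen=True)
class EpitopeInput:
    """A linear IgE epitope as catalogued (ID, sequence, source allergen)."""

    iedb_id: str
    sequence: str
    annotated_allergen: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, f"epitope {self.iedb_id}")
        )
        if len(self.sequence) < 3:
            raise ValidationError(
                f"epitope {self.iedb_id}: length {len(self.sequence)} < 3"
            )


@dataclass
class ScoreRow:
    """Scores for one entity (whole protein or merged epitope region)."""

    entity_id: str
    entity_kind: str  # "protein" | "epitope"
    n_residues: int
    per_activity_A: dict[str, float]
    sum_A: float
    dht_percent: float
    per_activity_AE: dict[str, float]
    sum_AE: float
    domain_set: str = "none"  # "1" | "2" | "3a" | "3b" | "none"


@dataclass
class ScoreTable:
    rows: list[ScoreRow] = field(default_factory=list)

    def validate(self) -> None:
        for r in self.rows:
            if abs(sum(r.per_activity_A.values()) - r.sum_A) > 1e-9:
                raise ValidationError(f"{r.entity_id}: sum_A != sum of per-activity A")
            if abs(sum(r.per_activity_AE.values()) - r.sum_AE) > 1e-9:
                raise ValidationError(f"{r.entity_id}: sum_AE != sum of per-activity A_E")
            if not 0.0 <= r.dht_percent <= 100.0:
                raise ValidationError(f"{r.entity_id}: DH_t outside [0, 100]")

    def activities(self) -> list[str]:
        labels: set[str] = set()
        for r in self.rows:
            labels.update(r.per_activity_A)
            labels.update(r.per_activity_AE)
        return sorted(labels)

    def to_frame(self) -> pd.DataFrame:
        acts = self.activities()
        records = []
        for r in self.rows:
            rec: dict[str, object] = {
                "entity_id": r.entity_id,
                "entity_kind": r.entity_kind,
                "N": r.n_residues,
                "DHt_percent": r.dht_percent,
                "sum_A": r.sum_A,
                "sum_AE": r.sum_AE,
                "domain_set": r.domain_set,
            }
            for a in acts:
                rec[f"A:{a}"] = r.per_activity_A.get(a, 0.0)
                rec[f"AE:{a}"] = r.per_activity_AE.get(a, 0.0)
            records.append(rec)
        cols = ["entity_id", "entity_kind", "N", "DHt_percent", "sum_A", "sum_AE", "domain_set"]
        cols += [f"A:{a}" for a in acts] + [f"AE:{a}" for a in acts]
        return pd.DataFrame.from_records(records, columns=cols)


@dataclass(frozen=True)
class EpitopeRegion:
    """A merged, protein-anchored epitope interval (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"region on {self.protein_id}: bad interval [{self.start}, {self.end}]"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"region on {self.protein_id}: sequence length != interval length"
            )
        if not self.member_ids:
            raise ValidationError(f"region on {self.protein_id}: no member ids")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects.

    Headers of the form ``accession|allergen_name|species`` populate all
    three fields; any other header is taken as both accession and name.
    Residues outside the 20-letter alphabet raise :class:`ValidationError`
    naming the entity and position, unless ``allow_ambiguous`` retains the
    B/J/X/Z/U/O codes (fragments containing them never match a reference
    peptide).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as fh:
        stripped = fh.read().strip()
    if stripped and not stripped.startswith(">"):
        raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise ParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        parts = rec.description.split("|")
        if len(parts) >= 3:
            accession, name, species = parts[0].strip(), parts[1].strip(), parts[2].strip()
        else:
            accession = rec.id.strip()
            name, species = accession, ""
        seq = _check_sequence(str(rec.seq), accession, allow_ambiguous)
        records.append(
            ProteinRecord(
                accession=accession, allergen_name=name, species=species, sequence=seq
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f"{r.accession}|{r.allergen_name}|{r.species}"
            fh.write(f">{header}\n{r.sequence}\n")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_activity_table(path: str | Path) -> ActivityReference:
    """Read a peptide-activity reference table (columns: peptide, activity[, source_id])."""
    df = _read_tsv(path, ["peptide", "activity"])
    if (df["activity"] == "").any():
        bad = int((df["activity"] == "").idxmax()) + 2  # +2: header + 1-based
        raise SchemaError(f"{path}: empty activity label at line {bad}")
    entries = [
        ActivityEntry(
            row["peptide"],
            row["activity"],
            row.get("source_id") or None,
        )
        for _, row in df.iterrows()
    ]
    return ActivityReference(entries)


def write_activity_table(reference: ActivityReference, path: str | Path) -> None:
    pd.DataFrame(
        [(e.peptide, e.activity, e.source_id or "") for e in reference.entries],
        columns=["peptide", "activity", "source_id"],
    ).to_csv(path, sep="\t", index=False)


def read_epitope_table(path: str | Path) -> list[EpitopeInput]:
    """Read linear epitopes (columns: iedb_id, sequence, annotated_allergen)."""
    df = _read_tsv(path, ["iedb_id", "sequence", "annotated_allergen"])
    ids = df["iedb_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate iedb_id(s) {sorted(dupes)}")
    return [
        EpitopeInput(row["iedb_id"], row["sequence"], row["annotated_allergen"])
        for _, row in df.iterrows()
    ]


def write_epitope_table(epitopes: Sequence[EpitopeInput], path: str | Path) -> None:
    pd.DataFrame(
        [(e.iedb_id, e.sequence, e.annotated_allergen) for e in epitopes],
        columns=["iedb_id", "sequence", "annotated_allergen"],
    ).to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read per-protein InterPro IDs (columns: accession, domain_ids semicolon-joined)."""
    df = _read_tsv(path, ["accession", "domain_ids"])
    out: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        ids = tuple(x.strip() for x in row["domain_ids"].split(";") if x.strip())
        out[row["accession"]] = ids
    return out


def write_regions(regions: Sequence[EpitopeRegion], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.protein_id, r.start, r.end, r.sequence, ";".join(r.member_ids))
            for r in regions
        ],
        columns=["protein_id", "start", "end", "sequence", "member_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[EpitopeRegion]:
    df = _read_tsv(path, ["protein_id", "start", "end", "sequence", "member_ids"])
    return [
        EpitopeRegion(
            row["protein_id"],
            int(row["start"]),
            int(row["end"]),
            row["sequence"],
            tuple(row["member_ids"].split(";")),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Score table serialization
# ---------------------------------------------------------------------------


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as TSV with a stable column order and 4-decimal scores."""
    table.validate()
    df = table.to_frame()
    float_cols = [c for c in df.columns if c not in ("entity_id", "entity_kind", "N", "domain_set")]
    for c in float_cols:
        df[c] = df[c].map(lambda v: f"{v:.{SCORE_DECIMALS}f}")
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> ScoreTable:
    df = _read_tsv(
        path,
        ["entity_id", "entity_kind", "N", "DHt_percent", "sum_A", "sum_AE", "domain_set"],
    )
    a_cols = [c for c in df.columns if c.startswith("A:")]
    ae_cols = [c for c in df.columns if c.startswith("AE:")]
    rows = []
    for _, row in df.iterrows():
        rows.append(
            ScoreRow(
                entity_id=row["entity_id"],
                entity_kind=row["entity_kind"],
                n_residues=int(row["N"]),
                per_activity_A={c[2:]: float(row[c]) for c in a_cols},
                sum_A=float(row["sum_A"]),
                dht_percent=float(row["DHt_percent"]),
                per_activity_AE={c[3:]: float(row[c]) for c in ae_cols},
                sum_AE=float(row["sum_AE"]),
                domain_set=row["domain_set"],
            )
        )
    return ScoreTable(rows)


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------


def load_tree_nut_allergens() -> pd.DataFrame:
    """The 17 tree-nut allergens studied (accession, names, InterPro IDs, set label).

    Columns: accession, allergen_name, species, protein_type,
    domain_ids (semicolon-joined InterPro IDs), domain_set (catalogued
    label, "none" for unclassified proteins).
    """
    with resources.files("nutpep.data").joinpath("tree_nut_allergens.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def tree_nut_domain_map() -> dict[str, tuple[str, ...]]:
    df = load_tree_nut_allergens()
    return {
        row["accession"]: tuple(x.strip() for x in row["domain_ids"].split(";"))
        for _, row in df.iterrows()
    }
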