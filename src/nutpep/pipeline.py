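"""End-to-end orchestration: scan → digest → epitopes → group statistics.

Whole proteins and merged epitope regions are scored by exactly the same
machinery — a region is scored as a standalone chain of N residues, its
flanking protein context ignored (cleavage at region termini therefore
follows the excised sequence, not the in-situ bonds; documented because
flanking residues could alter terminal cleavage in vivo). The
protein-versus-epitope comparison is thus a pure data slice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import epitopes as _epitopes
from . import scan as _scan
from . import stats as _stats
from .digest import (
    DEFAULT_ENZYME_NAMES,
    EnzymeRule,
    default_enzymes,
    digest as _digest_sequence,
    load_enzyme_table,
    per_activity_release,
    theoretical_dh,
)
from .io import (
    ActivityReference,
    EpitopeRegion,
    ProteinRecord,
    ScoreRow,
    ScoreTable,
    read_activity_table,
    read_domain_table,
    read_epitope_table,
    read_fasta,
    write_regions,
    write_score_table,
)

logger = logging.getLogger("nutpep")


@dataclass
class RunConfig:
    fasta: Path
    activities: Path
    epitopes: Path | None = None
    domains: Path | None = None
    enzyme_table: Path | None = None
    enzyme_names: tuple[str, ...] = DEFAULT_ENZYME_NAMES
    min_fragment_length: int = _scan.DEFAULT_MIN_FRAGMENT_LENGTH
    min_identity: float = 1.0
    merged_sets: bool = False
    out_dir: Path = Path("nutpep_out")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key-value config (``key = value`` lines, '#' comments)."""
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (x.strip() for x in line.split("=", 1))
            kv[k] = v
        def pop_path(key):
            return Path(kv.pop(key)) if key in kv else None
        kwargs: dict = {}
        for key in ("fasta", "activities", "epitopes", "domains", "enzyme_table", "out_dir"):
            p = pop_path(key)
            if p is not None:
                kwargs[key] = p
        if "enzymes" in kv:
            kwargs["enzyme_names"] = tuple(x.strip() for x in kv.pop("enzymes").split(","))
        if "min_fragment_length" in kv:
            kwargs["min_fragment_length"] = int(kv.pop("min_fragment_length"))
        if "min_identity" in kv:
            kwargs["min_identity"] = float(kv.pop("min_identity"))
        if "merged_sets" in kv:
            kwargs["merged_sets"] = kv.pop("merged_sets").lower() in ("1", "true", "yes")
        if kv:
            raise ValueError(f"{path}: unknown config key(s) {sorted(kv)}")
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("fasta", "activities", "epitopes", "domains", "enzyme_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config: {name} path {p} does not exist")


def score_entities(
    entities: Sequence[tuple[str, str, str]],
    reference: ActivityReference,
    enzymes: Sequence[EnzymeRule],
    min_fragment_length: int = _scan.DEFAULT_MIN_FRAGMENT_LENGTH,
) -> ScoreTable:
    """Score (entity_id, kind, sequence) triples with A/∑A, DH_t, A_E/∑A_E."""
    rows = []
    for entity_id, kind, sequence in entities:
        per_a = _scan.per_activity_frequencies(sequence, reference, min_fragment_length)
        per_ae = per_activity_release(
            sequence, enzymes, reference, min_fragment_length
        )
        result = _digest_sequence(sequence, enzymes)
        rows.append(
            ScoreRow(
                entity_id=entity_id,
                entity_kind=kind,
                n_residues=len(sequence),
                per_activity_A={a: float(v) for a, v in per_a.items()},
                sum_A=float(sum(per_a.values())),
                dht_percent=theoretical_dh(result),
                per_activity_AE={a: float(v) for a, v in per_ae.items()},
                sum_AE=float(sum(per_ae.values())),
            )
        )
    table = ScoreTable(rows)
    table.validate()
    return table


def score_proteins(
    proteins: Sequence[ProteinRecord],
    reference: ActivityReference,
    enzymes: Sequence[EnzymeRule],
    min_fragment_length: int = _scan.DEFAULT_MIN_FRAGMENT_LENGTH,
) -> ScoreTable:
    return score_entities(
        [(p.accession, "protein", p.sequence) for p in proteins],
        reference,
        enzymes,
        min_fragment_length,
    )


def score_regions(
    regions: Sequence[EpitopeRegion],
    reference: ActivityReference,
    enzymes: Sequence[EnzymeRule],
    min_fragment_length: int = _scan.DEFAULT_MIN_FRAGMENT_LENGTH,
) -> ScoreTable:
    return score_entities(
        [
            (f"{r.protein_id}:{r.start}-{r.end}", "epitope", r.sequence)
            for r in regions
        ],
        reference,
        enzymes,
        min_fragment_length,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all artifacts to ``config.out_dir``.

    Deterministic for fixed inputs. On failure, partial outputs are kept
    and a FAILED marker file records the error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: RunConfig, out: Path) -> Path:
    proteins = read_fasta(config.fasta)
    reference = read_activity_table(config.activities)
    if config.enzyme_table is not None:
        table = load_enzyme_table(config.enzyme_table)
        enzymes = [table[n] for n in config.enzyme_names]
    else:
        enzymes = default_enzymes(config.enzyme_names)

    protein_scores = score_proteins(
        proteins, reference, enzymes, config.min_fragment_length
    )

    domain_map: dict[str, tuple[str, ...]] = {}
    if config.domains is not None:
        domain_map = read_domain_table(config.domains)
    assignments = [
        _stats.assign_domain_set(domain_map.get(p.accession, p.domain_ids), p.accession)
        for p in proteins
    ]
    label_of = {a.entity_id: a for a in assignments}
    for row in protein_scores.rows:
        row.domain_set = label_of[row.entity_id].set_label
    write_score_table(protein_scores, out / "protein_scores.tsv")

    regions: list[EpitopeRegion] = []
    if config.epitopes is not None:
        epitope_inputs = read_epitope_table(config.epitopes)
        regions = _epitopes.preprocess_epitope_set(
            epitope_inputs, proteins, config.min_identity
        )
        write_regions(regions, out / "epitope_regions.tsv")
        if regions:
            region_scores = score_regions(
                regions, reference, enzymes, config.min_fragment_length
            )
            for row, region in zip(region_scores.rows, regions):
                row.domain_set = label_of[region.protein_id].set_label
            write_score_table(region_scores, out / "epitope_scores.tsv")
            bins = pd.DataFrame(
                {
                    "entity_id": [r.entity_id for r in region_scores.rows],
                    "sum_A": [f"{r.sum_A:.4f}" for r in region_scores.rows],
                    "interval": [
                        _stats.bin_epitope_sumA(r.sum_A) for r in region_scores.rows
                    ],
                }
            )
            bins.to_csv(out / "epitope_sumA_bins.tsv", sep="\t", index=False)
    else:
        logger.info("no epitope table given; protein-only run")

    def _write_group_outputs(
        scores: ScoreTable, assigns: list[_stats.DomainSetAssignment], prefix: str
    ) -> None:
        summaries = _stats.summarize_groups(scores, assigns, config.merged_sets)
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / f"{prefix}group_summary.tsv", sep="\t", index=False
        )
        comp_rows = []
        for score_name in _stats.SCORE_NAMES:
            comparisons = _stats.pairwise_compare(
                scores, assigns, score_name, config.merged_sets
            )
            comp_rows.extend(dataclasses.asdict(c) for c in comparisons)
            _stats.distance_matrix(comparisons).to_csv(
                out / f"{prefix}distance_{score_name}.tsv", sep="\t"
            )
        pd.DataFrame(comp_rows).to_csv(
            out / f"{prefix}comparisons.tsv", sep="\t", index=False
        )

    _write_group_outputs(protein_scores, assignments, "")
    if regions:
        region_assignments = [
            _stats.DomainSetAssignment(
                entity_id=f"{r.protein_id}:{r.start}-{r.end}",
                set_label=label_of[r.protein_id].set_label,
            )
            for r in regions
        ]
        _write_group_outputs(
            score_regions(regions, reference, enzymes, config.min_fragment_length),
            region_assignments,
            "epitope_",
        )

    manifest = {
        "nutpep_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "parameters": {
            "enzymes": list(config.enzyme_names),
            "min_fragment_length": config.min_fragment_length,
            "min_identity": config.min_identity,
            "merged_sets": config.merged_sets,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("fasta", config.fasta),
                ("activities", config.activities),
                ("epitopes", config.epitopes),
                ("domains", config.domains),
                ("enzyme_table", config.enzyme_table),
            )
            if p is not None
        },
        "n_proteins": len(proteins),
        "n_epitope_regions": len(regions),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
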