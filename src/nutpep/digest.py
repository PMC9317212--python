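"""Rule-based simulated proteolysis.

Each protease is modelled by single-position specificity: it hydrolyses
the bond C-terminal to any P1 residue in its set, unless the following
(P1′) residue is listed as an exclusion. Digestion by several enzymes is
simultaneous — the union of their cleavage sites — and exhaustive: every
susceptible bond is cut. From a digest follow

* the theoretical degree of hydrolysis DH_t = d/D × 100%, with d the
  number of hydrolysed bonds and D = N − 1 the total number of peptide
  bonds, and
* the frequency of release A_E = d/N, with d here the number of released
  fragments whose sequence equals a reference peptide of the given
  activity; ∑A_E sums A_E over all activities.

The default enzyme table (pepsin at pH > 2, trypsin, chymotrypsin A) is
shipped as TSV data and can be replaced without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import (
    ActivityReference,
    DomainError,
    SchemaError,
    ValidationError,
    _check_sequence,
)
from .scan import DEFAULT_MIN_FRAGMENT_LENGTH

DEFAULT_ENZYME_NAMES = ("pepsin_ph_gt2", "trypsin", "chymotrypsin_a")


@dataclass(frozen=True)
class EnzymeRule:
    """A protease's cleavage specificity (cuts C-terminal to P1 residues)."""

    name: str
    ec_number: str
    biopep_id: int
    p1_residues: frozenset[str]
    p1prime_exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValidationError(f"enzyme {self.name}: empty P1 residue set")


def load_enzyme_table(path: str | Path | None = None) -> dict[str, EnzymeRule]:
    """Load protease rules from TSV (columns: name, ec_number, biopep_id,
    p1_residues, p1prime_exclusions); defaults to the packaged table."""
    if path is None:
        with resources.files("nutpep.data").joinpath("enzymes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "ec_number", "biopep_id", "p1_residues"}
    if not required.issubset(df.columns):
        raise SchemaError(f"enzyme table missing columns {sorted(required - set(df.columns))}")
    rules = {}
    for _, row in df.iterrows():
        excl = row.get("p1prime_exclusions", "")
        if not isinstance(excl, str):
            excl = ""
        rules[row["name"]] = EnzymeRule(
            name=row["name"],
            ec_number=row["ec_number"],
            biopep_id=int(row["biopep_id"]),
            p1_residues=frozenset(row["p1_residues"].strip()),
            p1prime_exclusions=frozenset(excl.strip()),
        )
    return rules


def default_enzymes(names: Sequence[str] = DEFAULT_ENZYME_NAMES) -> list[EnzymeRule]:
    table = load_enzyme_table()
    missing = [n for n in names if n not in table]
    if missing:
        raise DomainError(f"unknown enzyme name(s) {missing}; known: {sorted(table)}")
    return [table[n] for n in names]


@dataclass(frozen=True)
class DigestResult:
    """Fragments and cut sites of one exhaustive digest.

    ``cut_sites`` are bond indices: bond i joins residues i and i+1
    (1-based), so valid indices run 1..N−1. Fragments carry 1-based
    inclusive coordinates and concatenate to the input sequence.
    """

    sequence: str
    fragments: tuple[tuple[str, int, int], ...]
    cut_sites: tuple[int, ...]

    @property
    def d_bonds(self) -> int:
        return len(self.cut_sites)

    @property
    def D_bonds(self) -> int:
        return len(self.sequence) - 1


def cleavage_sites(sequence: str, enzymes: Sequence[EnzymeRule]) -> list[int]:
    """Bond indices hydrolysed by any of ``enzymes`` (deduplicated, sorted).

    Bond i is cut iff residue i is a P1 residue of some enzyme and residue
    i+1 is not in that enzyme's P1′ exclusions. The C-terminal residue has
    no following bond and generates no site.
    """
    if not enzymes:
        raise DomainError("at least one enzyme is required")
    sequence = _check_sequence(sequence, "substrate", allow_ambiguous=True)
    sites: set[int] = set()
    for enz in enzymes:
        for i in range(1, len(sequence)):  # bond i joins residues i, i+1
            if sequence[i - 1] in enz.p1_residues and sequence[i] not in enz.p1prime_exclusions:
                sites.add(i)
    return sorted(sites)


def digest(sequence: str, enzymes: Sequence[EnzymeRule]) -> DigestResult:
    """Exhaustively digest ``sequence``; fragments are maximal runs between cuts."""
    sequence = _check_sequence(sequence, "substrate", allow_ambiguous=True)
    sites = cleavage_sites(sequence, enzymes)
    bounds = [0] + sites + [len(sequence)]
    fragments = tuple(
        (sequence[a:b], a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return DigestResult(sequence=sequence, fragments=fragments, cut_sites=tuple(sites))


def theoretical_dh(result: DigestResult) -> float:
    """Theoretical degree of hydrolysis DH_t = d/D × 100, in percent."""
    if result.D_bonds < 1:
        raise DomainError("DH_t undefined for a single-residue chain (no peptide bonds)")
    return 100.0 * result.d_bonds / result.D_bonds


def release_frequency(
    sequence: str,
    enzymes: Sequence[EnzymeRule],
    reference: ActivityReference,
    activity: str,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> Fraction:
    """Frequency of release A_E = d/N for one activity.

    ``d`` counts digest fragments whose sequence equals a reference
    peptide carrying the activity; each released fragment occurrence
    counts once. A reference peptide present in the chain but bisected by
    a cut site contributes nothing.
    """
    if activity not in reference.activities:
        raise DomainError(f"unknown activity label {activity!r}")
    peptides = {
        e.peptide
        for e in reference.restricted(min_fragment_length).entries
        if e.activity == activity
    }
    result = digest(sequence, enzymes)
    d = sum(1 for frag, _, _ in result.fragments if frag in peptides)
    return Fraction(d, len(result.sequence))


def total_release_frequency(
    sequence: str,
    enzymes: Sequence[EnzymeRule],
    reference: ActivityReference,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> Fraction:
    """Total frequency of release ∑A_E, summed over every activity label."""
    return sum(
        (
            release_frequency(sequence, enzymes, reference, act, min_fragment_length)
            for act in reference.activities
        ),
        Fraction(0),
    )


def per_activity_release(
    sequence: str,
    enzymes: Sequence[EnzymeRule],
    reference: ActivityReference,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> dict[str, Fraction]:
    """A_E for every activity label from a single digest pass."""
    result = digest(sequence, enzymes)
    restricted = reference.restricted(min_fragment_length)
    by_activity: dict[str, set[str]] = {act: set() for act in reference.activities}
    for e in restricted.entries:
        by_activity[e.activity].add(e.peptide)
    n = len(result.sequence)
    out = {}
    for act in reference.activities:
        peps = by_activity.get(act, set())
        d = sum(1 for frag, _, _ in result.fragments if frag in peps)
        out[act] = Fraction(d, n)
    return out
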