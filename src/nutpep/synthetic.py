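"""Synthetic inputs with planted ground truth.

Every generator stands in for a database retrieval: a peptide-activity
reference dominated by di-/tripeptides (the composition of curated
bioactive-peptide collections), proteins carrying planted bioactive
fragments at recorded positions, chains with cleavage sites at chosen
bonds, and epitope sets with controlled overlap structure. Planting uses
a background alphabet disjoint from the planted peptides' residues, with
at least one background residue between plants, so the recorded truth is
exact by construction rather than probabilistic. Each generator verifies
its own truth by running the corresponding pipeline operation before
returning, and fails loudly on any mismatch.

All randomness flows through one ``numpy.random.Generator`` seeded per
call, so outputs are bit-stable for a fixed (parameters, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .digest import EnzymeRule, cleavage_sites as _cleavage_sites, default_enzymes as _default_enzymes
from . import epitopes as _epitopes
from . import scan as _scan
from .io import (
    ActivityEntry,
    ActivityReference,
    DomainError,
    EpitopeInput,
    EpitopeRegion,
    ProteinRecord,
    STANDARD_RESIDUES,
)

ALPHABET = "".join(sorted(STANDARD_RESIDUES))

#: Default peptide-length distribution: mass concentrated on di-/tripeptides.
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {2: 0.70, 3: 0.25, 4: 0.05}

#: Default activity labels, after the most abundant catalogued classes.
DEFAULT_ACTIVITIES = (
    "ACE inhibitor",
    "DPP-IV inhibitor",
    "DPP-III inhibitor",
    "antioxidative",
)


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time, verified by the pipeline."""

    seed: int
    planted_matches: list[tuple[str, str, int, int]] = field(default_factory=list)
    planted_cut_sites: list[tuple[str, int]] = field(default_factory=list)
    expected_A: dict[tuple[str, str], Fraction] = field(default_factory=dict)
    expected_DHt: dict[str, float] = field(default_factory=dict)
    expected_regions: list[EpitopeRegion] = field(default_factory=list)


class TruthMismatch(AssertionError):
    """A generator's planted truth disagreed with the pipeline — a bug."""


def generate_reference(
    n_peptides: int,
    length_weights: Mapping[int, float] | None = None,
    n_activities: int = len(DEFAULT_ACTIVITIES),
    seed: int = 0,
    activities: Sequence[str] | None = None,
    alphabet: str = ALPHABET,
) -> ActivityReference:
    """Random peptide-activity reference; peptides unique per activity."""
    weights = dict(length_weights or DEFAULT_LENGTH_WEIGHTS)
    if n_peptides < 1:
        raise DomainError("n_peptides must be >= 1")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise DomainError("length weights must sum to 1")
    if activities is None:
        activities = [
            DEFAULT_ACTIVITIES[i] if i < len(DEFAULT_ACTIVITIES) else f"activity_{i}"
            for i in range(n_activities)
        ]
    rng = np.random.default_rng(seed)
    lengths = sorted(weights)
    probs = np.array([weights[L] for L in lengths])
    per_activity = -(-n_peptides // len(activities))  # ceil
    budget = sum(len(alphabet) ** L for L, w in weights.items() if w > 0)
    if per_activity > budget:
        raise DomainError(
            f"cannot draw {per_activity} unique peptides from a budget of {budget}"
        )
    entries: list[ActivityEntry] = []
    remaining = n_peptides
    for act in activities:
        want = min(per_activity, remaining)
        seen: set[str] = set()
        while len(seen) < want:
            L = int(rng.choice(lengths, p=probs))
            pep = "".join(rng.choice(list(alphabet), size=L))
            seen.add(pep)
        entries.extend(ActivityEntry(p, act) for p in sorted(seen))
        remaining -= want
        if remaining == 0:
            break
    return ActivityReference(entries)


def plantable_reference(
    n_peptides: int,
    seed: int = 0,
    background_alphabet: str = "AGST",
    length_weights: Mapping[int, float] | None = None,
) -> ActivityReference:
    """Reference safe for exact planting against ``background_alphabet``.

    Peptides are drawn from the complementary alphabet and kept
    substring-free (no peptide contained in another), so planting every
    entry with disjoint-alphabet backgrounds yields exactly the planted
    occurrence counts — no accidental or nested matches.
    """
    alphabet = "".join(sorted(STANDARD_RESIDUES - set(background_alphabet)))
    raw = generate_reference(
        2 * n_peptides, length_weights=length_weights, seed=seed, alphabet=alphabet
    )
    kept: list[ActivityEntry] = []
    for e in raw.entries:
        if any(e.peptide in k.peptide or k.peptide in e.peptide for k in kept):
            continue
        kept.append(e)
        if len(kept) == n_peptides:
            break
    if len(kept) < n_peptides:
        raise DomainError(
            f"could only assemble {len(kept)} substring-free peptides of {n_peptides}"
        )
    return ActivityReference(kept)


def _place_nonoverlapping(
    rng: np.random.Generator, length: int, piece_lengths: Sequence[int]
) -> list[int]:
    """Random 0-based start offsets with >= 1 residue between pieces."""
    k = len(piece_lengths)
    slack = length - sum(piece_lengths) - (k - 1)
    if slack < 0:
        raise DomainError(
            f"cannot place pieces of total length {sum(piece_lengths)} "
            f"with gaps in a chain of {length}"
        )
    # distribute `slack` extra background residues over k+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    starts = []
    pos = 0
    prev_cut = 0
    for i, L in enumerate(piece_lengths):
        gap = int(cuts[i]) - prev_cut + (1 if i > 0 else 0)
        pos += gap
        starts.append(pos)
        pos += L
        prev_cut = int(cuts[i])
    return starts


def generate_protein_with_plants(
    length: int,
    plants: Sequence[tuple[str, int]],
    background_alphabet: Sequence[str] = "AGST",
    seed: int = 0,
    reference: ActivityReference | None = None,
    accession: str = "SYN0001",
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Protein of ``length`` residues with exact planted fragment copies.

    Each (peptide, count) plant appears exactly ``count`` times at
    recorded, non-overlapping positions separated by background residues
    whose alphabet is disjoint from every planted peptide — no accidental
    occurrences are possible. ``expected_A`` records count/length per
    activity of the verification reference (one synthetic activity per
    peptide when no reference is given).
    """
    rng = np.random.default_rng(seed)
    background = sorted(set(background_alphabet))
    plant_residues = {ch for pep, _ in plants for ch in pep}
    if plant_residues & set(background):
        raise DomainError("background alphabet must be disjoint from planted residues")
    if not set(background) <= STANDARD_RESIDUES:
        raise DomainError("background alphabet contains non-standard residues")
    copies = [pep for pep, count in plants for _ in range(count)]
    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]
    starts = _place_nonoverlapping(rng, length, [len(p) for p in copies])
    chars = list(rng.choice(background, size=length))
    truth = SyntheticTruth(seed=seed)
    if reference is None:
        reference = ActivityReference(
            ActivityEntry(pep, f"planted:{pep}") for pep, _ in plants
        )
    activity_of: dict[str, list[str]] = {}
    for e in reference.entries:
        activity_of.setdefault(e.peptide, []).append(e.activity)
    for pep, start0 in zip(copies, starts):
        chars[start0 : start0 + len(pep)] = list(pep)
        for act in activity_of.get(pep, []):
            truth.planted_matches.append((accession, act, start0 + 1, start0 + len(pep)))
    sequence = "".join(chars)
    record = ProteinRecord(
        accession=accession, allergen_name=accession, sequence=sequence
    )
    counts: dict[str, int] = {}
    for _, act, _, _ in truth.planted_matches:
        counts[act] = counts.get(act, 0) + 1
    for act in reference.activities:
        truth.expected_A[(accession, act)] = Fraction(counts.get(act, 0), length)
    _validate_plants(record, reference, truth)
    return record, truth


def _validate_plants(
    record: ProteinRecord, reference: ActivityReference, truth: SyntheticTruth
) -> None:
    min_len = min(len(e.peptide) for e in reference.entries)
    observed = _scan.per_activity_frequencies(record.sequence, reference, min_len)
    for (acc, act), expected in truth.expected_A.items():
        if observed[act] != expected:
            raise TruthMismatch(
                f"{acc}/{act}: planted A={expected} but scan found {observed[act]}"
            )


def generate_cleavage_layout(
    n_fragments: int,
    fragment_length_range: tuple[int, int] = (1, 5),
    seed: int = 0,
    accession: str = "SYNDIG1",
) -> tuple[ProteinRecord, list[EnzymeRule], SyntheticTruth]:
    """Chain whose trypsin cut sites (and hence digest) are known exactly.

    Fragments of random length over non-cleavable residues are joined by
    K residues, so bonds after each K — and no others — are cut sites.
    Records the planted bond indices and the implied DH_t.
    """
    if n_fragments < 1:
        raise DomainError("need at least one fragment")
    lo, hi = fragment_length_range
    if lo < 1 or hi < lo:
        raise DomainError("bad fragment length range")
    rng = np.random.default_rng(seed)
    inert = "AGSTVNQ"  # no trypsin P1 residues
    pieces = [
        "".join(rng.choice(list(inert), size=int(rng.integers(lo, hi + 1))))
        for _ in range(n_fragments)
    ]
    sequence = "K".join(pieces) if n_fragments > 1 else pieces[0]
    # a K joins piece i to piece i+1; the bond after each K is cut
    truth = SyntheticTruth(seed=seed)
    pos = 0
    for piece in pieces[:-1]:
        pos += len(piece) + 1  # the K residue index (1-based)
        truth.planted_cut_sites.append((accession, pos))
    trypsin = _default_enzymes(["trypsin"])
    record = ProteinRecord(accession=accession, allergen_name=accession, sequence=sequence)
    sites = _cleavage_sites(sequence, trypsin)
    expected_sites = [b for _, b in truth.planted_cut_sites]
    if sites != expected_sites:
        raise TruthMismatch(f"planted sites {expected_sites} but digest found {sites}")
    if len(sequence) > 1:
        truth.expected_DHt[accession] = 100.0 * len(sites) / (len(sequence) - 1)
    return record, trypsin, truth


def generate_epitope_scenario(
    protein_length: int,
    n_epitopes: int,
    overlap_profile: str,
    seed: int = 0,
    epitope_length: int = 10,
    accession: str = "SYNEPI1",
) -> tuple[ProteinRecord, list[EpitopeInput], SyntheticTruth]:
    """Protein plus epitopes with a controlled overlap layout.

    ``overlap_profile``: "chained" — every epitope overlaps the next, all
    merge to one region; "disjoint" — gaps >= 2, nothing merges;
    "adjacent" — abutting pairs, each pair merges. Expected merged
    regions are recorded and verified against the mapping/merge pipeline.
    """
    if overlap_profile not in ("disjoint", "chained", "adjacent"):
        raise DomainError(f"unknown overlap profile {overlap_profile!r}")
    if n_epitopes < 1:
        raise DomainError("need at least one epitope")
    if overlap_profile == "adjacent" and n_epitopes % 2:
        raise DomainError("adjacent profile needs an even number of epitopes")
    rng = np.random.default_rng(seed)
    L = epitope_length
    starts0: list[int] = []
    if overlap_profile == "chained":
        step = max(1, L // 2)  # overlap of L - step >= 1
        starts0 = [i * step for i in range(n_epitopes)]
    elif overlap_profile == "disjoint":
        starts0 = [i * (L + 2) for i in range(n_epitopes)]
    else:  # adjacent pairs, pairs separated by a 2-residue gap
        for pair in range(n_epitopes // 2):
            base = pair * (2 * L + 2)
            starts0.extend([base, base + L])
    span = starts0[-1] + L
    if span > protein_length:
        raise DomainError(
            f"layout needs {span} residues but protein_length is {protein_length}"
        )
    shift = int(rng.integers(0, protein_length - span + 1))
    starts0 = [s + shift for s in starts0]
    # sequence with all 20-residue diversity; epitopes are its substrings,
    # made unique by construction (random sequence of this length collides
    # with vanishing probability; verified below anyway)
    sequence = "".join(rng.choice(list(ALPHABET), size=protein_length))
    record = ProteinRecord(accession=accession, allergen_name=accession, sequence=sequence)
    epitopes = [
        EpitopeInput(
            iedb_id=f"SYNEP{i:04d}",
            sequence=sequence[s : s + L],
            annotated_allergen=accession,
        )
        for i, s in enumerate(starts0)
    ]
    truth = SyntheticTruth(seed=seed)
    if overlap_profile == "chained":
        intervals = [(starts0[0] + 1, starts0[-1] + L)]
        members = [tuple(sorted(e.iedb_id for e in epitopes))]
    elif overlap_profile == "disjoint":
        intervals = [(s + 1, s + L) for s in starts0]
        members = [(e.iedb_id,) for e in epitopes]
    else:
        intervals = [
            (starts0[i] + 1, starts0[i + 1] + L) for i in range(0, len(starts0), 2)
        ]
        members = [
            tuple(sorted((epitopes[i].iedb_id, epitopes[i + 1].iedb_id)))
            for i in range(0, len(starts0), 2)
        ]
    truth.expected_regions = [
        EpitopeRegion(
            protein_id=accession,
            start=a,
            end=b,
            sequence=sequence[a - 1 : b],
            member_ids=m,
        )
        for (a, b), m in zip(intervals, members)
    ]
    observed = _epitopes.preprocess_epitope_set(epitopes, [record], min_identity=1.0)
    if observed != truth.expected_regions:
        raise TruthMismatch(
            f"{overlap_profile} layout: expected {len(truth.expected_regions)} regions, "
            f"pipeline produced {len(observed)}"
        )
    return record, epitopes, truth
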