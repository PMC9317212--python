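"""Mapping linear IgE epitopes onto proteins and merging them into regions.

Epitopes are first located on their annotated source protein by exact
substring search, then transferred to homologous proteins of other
species. Cross-species transfer uses Smith–Waterman local alignment with
the PAM30 substitution matrix (gap open 9, gap extend 1 — the standard
short-peptide settings), which bounds from below the sensitivity of a
word-seeded heuristic search at word size 3. Identity is measured as the
number of identically aligned residues divided by the full epitope
length, so identity 1.0 means the whole epitope is matched without gaps
or substitutions; the default transfer threshold is identity 1.0.

Mapped placements that overlap by at least one residue, or that directly
abut (gap 0), are merged into longer non-redundant regions, mirroring
the overlap structure of peptide-scanning epitope mapping. A one-residue
gap does not merge.
"""

from __future__ import annotations

import logging
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import (
    DomainError,
    EpitopeInput,
    EpitopeRegion,
    ProteinRecord,
    ValidationError,
)
from dataclasses import dataclass

logger = logging.getLogger("nutpep")

GAP_OPEN = 9
GAP_EXTEND = 1
MIN_EPITOPE_LENGTH = 3  # below the seeding word size, alignment is meaningless


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment placement of an epitope on a subject protein."""

    query_id: str
    subject_protein: str
    subject_start: int
    subject_end: int
    identity_fraction: float
    score: int

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValidationError("AlignmentHit: start > end")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("PAM30"),
        open_gap_score=-GAP_OPEN,
        extend_gap_score=-GAP_EXTEND,
    )
    return aligner


def locate_exact(epitope: EpitopeInput, protein: ProteinRecord) -> list[EpitopeRegion]:
    """One region per exact substring occurrence of the epitope, sorted by start."""
    regions = []
    seq, pat = protein.sequence, epitope.sequence
    i = seq.find(pat)
    while i != -1:
        regions.append(
            EpitopeRegion(
                protein_id=protein.accession,
                start=i + 1,
                end=i + len(pat),
                sequence=pat,
                member_ids=(epitope.iedb_id,),
            )
        )
        i = seq.find(pat, i + 1)
    return regions


def cross_species_hits(
    epitope: EpitopeInput,
    proteins: Sequence[ProteinRecord],
    min_identity: float,
) -> list[AlignmentHit]:
    """Smith–Waterman PAM30 hits of an epitope against each protein.

    ``identity_fraction`` is identical residues over the epitope length,
    so full-length exact matches — and only those — score 1.0. Hits at or
    above ``min_identity`` are returned, the best hit per protein first,
    ordered by decreasing score.
    """
    if not 0 < min_identity <= 1:
        raise DomainError("min_identity must be in (0, 1]")
    if len(epitope.sequence) < MIN_EPITOPE_LENGTH:
        raise DomainError(
            f"epitope {epitope.iedb_id} shorter than {MIN_EPITOPE_LENGTH} residues"
        )
    aligner = _aligner()
    hits = []
    for protein in proteins:
        alignments = aligner.align(epitope.sequence, protein.sequence)
        try:
            best = alignments[0]
        except IndexError:
            continue
        q_blocks, s_blocks = best.aligned[0], best.aligned[1]
        identical = 0
        for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
            for k in range(qb - qa):
                if epitope.sequence[qa + k] == protein.sequence[sa + k]:
                    identical += 1
        identity = identical / len(epitope.sequence)
        if identity >= min_identity and len(s_blocks):
            hits.append(
                AlignmentHit(
                    query_id=epitope.iedb_id,
                    subject_protein=protein.accession,
                    subject_start=int(s_blocks[0][0]) + 1,
                    subject_end=int(s_blocks[-1][1]),
                    identity_fraction=identity,
                    score=int(best.score),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_protein))
    return hits


def merge_regions(regions: Sequence[EpitopeRegion]) -> list[EpitopeRegion]:
    """Merge overlapping (≥1 residue) and abutting (gap 0) regions.

    All regions must be anchored to the same protein. The merged
    sequence is stitched from the members' sequences; member IDs are the
    sorted union. Idempotent and order-invariant; output is sorted and
    pairwise non-overlapping, non-adjacent.
    """
    if not regions:
        return []
    proteins = {r.protein_id for r in regions}
    if len(proteins) > 1:
        raise DomainError(f"regions from multiple proteins in one call: {sorted(proteins)}")
    ordered = sorted(regions, key=lambda r: (r.start, r.end))
    clusters: list[list[EpitopeRegion]] = [[ordered[0]]]
    reach = ordered[0].end
    for r in ordered[1:]:
        if r.start <= reach + 1:  # overlap or gap 0
            clusters[-1].append(r)
        else:
            clusters.append([r])
        reach = max(reach, r.end)
    merged = []
    for cluster in clusters:
        start = min(r.start for r in cluster)
        end = max(r.end for r in cluster)
        chars: dict[int, str] = {}
        for r in cluster:
            for offset, ch in enumerate(r.sequence):
                pos = r.start + offset
                if chars.setdefault(pos, ch) != ch:
                    raise ValidationError(
                        f"inconsistent residue at position {pos} on {r.protein_id}"
                    )
        sequence = "".join(chars[p] for p in range(start, end + 1))
        members = tuple(sorted({m for r in cluster for m in r.member_ids}))
        merged.append(
            EpitopeRegion(
                protein_id=cluster[0].protein_id,
                start=start,
                end=end,
                sequence=sequence,
                member_ids=members,
            )
        )
    return merged


def preprocess_epitope_set(
    epitopes: Sequence[EpitopeInput],
    proteins: Sequence[ProteinRecord],
    min_identity: float = 1.0,
) -> list[EpitopeRegion]:
    """Map all epitopes onto all proteins and merge into non-redundant regions.

    Each epitope is placed exactly on its annotated allergen (matched by
    allergen name or accession; a missing allergen logs a warning), then
    transferred to every other protein — by exact substring search at the
    default ``min_identity`` of 1.0, or by PAM30 local alignment below it.
    Placements are merged per protein.
    """
    by_protein: dict[str, list[EpitopeRegion]] = {}
    index = {p.accession: p for p in proteins}
    index.update({p.allergen_name: p for p in proteins if p.allergen_name})
    for epitope in epitopes:
        placed_on: set[str] = set()
        source = index.get(epitope.annotated_allergen)
        if source is None:
            logger.warning(
                "epitope %s: annotated allergen %r not in protein set; "
                "mapping cross-species only",
                epitope.iedb_id,
                epitope.annotated_allergen,
            )
        else:
            for region in locate_exact(epitope, source):
                by_protein.setdefault(source.accession, []).append(region)
                placed_on.add(source.accession)
        others = [p for p in proteins if p.accession not in placed_on]
        if min_identity >= 1.0:
            for protein in others:
                for region in locate_exact(epitope, protein):
                    by_protein.setdefault(protein.accession, []).append(region)
        else:
            for hit in cross_species_hits(epitope, others, min_identity):
                protein = index[hit.subject_protein]
                by_protein.setdefault(protein.accession, []).append(
                    EpitopeRegion(
                        protein_id=protein.accession,
                        start=hit.subject_start,
                        end=hit.subject_end,
                        sequence=protein.sequence[hit.subject_start - 1 : hit.subject_end],
                        member_ids=(epitope.iedb_id,),
                    )
                )
    out: list[EpitopeRegion] = []
    for accession in sorted(by_protein):
        out.extend(merge_regions(by_protein[accession]))
    return out
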