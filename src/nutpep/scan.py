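"""Occurrence profiling of bioactive fragments in a protein chain.

A protein of N residues is scanned for exact substring occurrences of
every reference peptide. The frequency of occurrence of fragments with a
given activity is A = a/N, where a counts every occurrence (overlapping
and repeated occurrences included) of every reference peptide carrying
that activity. The total frequency ∑A sums A over all activity labels.

Single-residue reference entries are excluded by default
(``min_fragment_length=2``): dipeptides are the shortest fragment class
that dominates curated bioactive-peptide collections, and free residues
would swamp the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .io import ActivityReference, DomainError, ValidationError, _check_sequence

DEFAULT_MIN_FRAGMENT_LENGTH = 2


@dataclass(frozen=True)
class FragmentMatch:
    """One occurrence of a reference peptide (1-based inclusive coordinates)."""

    peptide: str
    activity: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValidationError("FragmentMatch: interval length != peptide length")


def _occurrences(sequence: str, peptide: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence."""
    starts = []
    i = sequence.find(peptide)
    while i != -1:
        starts.append(i + 1)
        i = sequence.find(peptide, i + 1)
    return starts


def profile(
    sequence: str,
    reference: ActivityReference,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> list[FragmentMatch]:
    """Report every occurrence of every reference peptide in ``sequence``.

    One :class:`FragmentMatch` per (peptide, activity, start); a peptide
    annotated under two activities yields a match per activity. Output is
    sorted by (start, end, activity).
    """
    sequence = _check_sequence(sequence, "query", allow_ambiguous=True)
    matches = []
    for entry in reference.restricted(min_fragment_length).entries:
        for start in _occurrences(sequence, entry.peptide):
            matches.append(
                FragmentMatch(entry.peptide, entry.activity, start, start + len(entry.peptide) - 1)
            )
    matches.sort(key=lambda m: (m.start, m.end, m.activity))
    return matches


def activity_frequency(
    sequence: str,
    reference: ActivityReference,
    activity: str,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> Fraction:
    """Frequency of occurrence A = a/N for one activity label.

    ``a`` is the number of fragment occurrences with the given activity,
    ``N`` the chain length. Exact rational arithmetic; callers render to
    4 decimals at output time.
    """
    if activity not in reference.activities:
        raise DomainError(f"unknown activity label {activity!r}")
    matches = profile(sequence, reference, min_fragment_length)
    a = sum(1 for m in matches if m.activity == activity)
    return Fraction(a, len("".join(sequence.split())))


def total_frequency(
    sequence: str,
    reference: ActivityReference,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> Fraction:
    """Total frequency of occurrence ∑A, summed over every activity label."""
    return sum(
        (
            activity_frequency(sequence, reference, act, min_fragment_length)
            for act in reference.activities
        ),
        Fraction(0),
    )


def per_activity_frequencies(
    sequence: str,
    reference: ActivityReference,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> dict[str, Fraction]:
    """A for every activity label in one scan (single profile pass)."""
    n = len("".join(sequence.split()))
    counts = {act: 0 for act in reference.activities}
    for m in profile(sequence, reference, min_fragment_length):
        counts[m.activity] += 1
    return {act: Fraction(c, n) for act, c in counts.items()}
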