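import collections

import numpy as np
import pytest

from nutpep import ActivityEntry, ActivityReference, default_enzymes


@pytest.fixture
def small_reference():
    """VW (ACE) and YP (DPP-IV): the minimal two-activity reference."""
    return ActivityReference(
        [ActivityEntry("VW", "ACE"), ActivityEntry("YP", "DPP-IV")]
    )


@pytest.fixture
def trypsin():
    return default_enzymes(["trypsin"])


@pytest.fixture
def gut_enzymes():
    """Pepsin (pH > 2) + trypsin + chymotrypsin A, the digestive-tract set."""
    return default_enzymes()


def brute_force_activity_counts(sequence, reference, min_fragment_length=2):
    """Independent oracle: enumerate every substring window per peptide."""
    counts = collections.Counter()
    for entry in reference.entries:
        if len(entry.peptide) < min_fragment_length:
            continue
        L = len(entry.peptide)
        for i in range(len(sequence) - L + 1):
            if sequence[i : i + L] == entry.peptide:
                counts[entry.activity] += 1
    return counts


def brute_force_cut_sites(sequence, enzymes):
    """Independent oracle: test every bond against every enzyme rule."""
    sites = set()
    for i in range(1, len(sequence)):
        for enz in enzymes:
            if sequence[i - 1] in enz.p1_residues and sequence[i] not in enz.p1prime_exclusions:
                sites.add(i)
    return sorted(sites)


def random_reference(rng: np.random.Generator, n_peptides: int) -> ActivityReference:
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    activities = ["ACE", "DPP-IV", "antiox"]
    entries = []
    for _ in range(n_peptides):
        L = int(rng.integers(2, 5))
        pep = "".join(rng.choice(alphabet, size=L))
        entries.append(ActivityEntry(pep, activities[int(rng.integers(0, 3))]))
    return ActivityReference(entries)


def random_sequence(rng: np.random.Generator, max_len: int = 200) -> str:
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(alphabet, size=n))
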