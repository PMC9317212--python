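"""Domain-set classification and group-comparison statistics.

Tree-nut seed-storage allergens are grouped by their InterPro domains:

* set 1 — napin (2S albumin) proteins: IPR036312, IPR016140, IPR000617;
* set 2 — cupin proteins that also carry the vicilin N-terminal domain
  IPR006792 (7S vicilins of pecan and walnut);
* set 3a — cupin 1 proteins without the vicilin N-terminal domain
  (IPR006045, IPR014710, IPR011051);
* set 3b — as 3a plus the 11S seed-storage domains IPR022379/IPR006044;
* set 3 — the merged sets 3a and 3b (the cupin 1 family);
* none — proteins outside these families (nsLTP, superoxide dismutase).

Group means and sample standard deviations of ∑A, DH_t and ∑A_E are
compared pairwise by two-sided Welch t-tests at p < 0.05 (no multiple-
testing correction; the number of comparisons is reported so users can
apply their own), and between-group distances are absolute differences
of scalar group means. Epitope ∑A values are additionally binned into
the four fixed intervals used for heat-map classification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DomainError, ScoreTable, ValidationError

logger = logging.getLogger("nutpep")

SIGNIFICANCE_LEVEL = 0.05

SET1_IDS = frozenset({"IPR036312", "IPR016140", "IPR000617"})
SET2_IDS = frozenset({"IPR006045", "IPR014710", "IPR011051", "IPR006792"})
SET3A_IDS = frozenset({"IPR006045", "IPR014710", "IPR011051"})
SET3B_IDS = frozenset({"IPR022379", "IPR006044", "IPR006045", "IPR014710", "IPR011051"})

NAPIN_ID = "IPR000617"
VICILIN_NTERM_ID = "IPR006792"
CUPIN1_ID = "IPR006045"
LEGUMIN_IDS = frozenset({"IPR006044", "IPR022379"})

#: ∑A intervals used to classify epitopes (inclusive printed endpoints).
SUM_A_INTERVALS = (
    (0.1, 0.5999),
    (0.6000, 1.0999),
    (1.1000, 1.5999),
    (1.6000, 2.1000),
)


@dataclass(frozen=True)
class DomainSetAssignment:
    entity_id: str
    set_label: str  # "1" | "2" | "3a" | "3b" | "none"

    @property
    def merged_label(self) -> str:
        return "3" if self.set_label in ("3a", "3b") else self.set_label


def assign_domain_set(domain_ids: Sequence[str], entity_id: str = "") -> DomainSetAssignment:
    """Classify a protein by its InterPro IDs.

    Priority: napin domain → set 1; vicilin N-terminal domain → set 2;
    cupin 1 with an 11S seed-storage domain → set 3b; cupin 1 alone →
    set 3a; anything else → none.
    """
    ids = set(domain_ids)
    if NAPIN_ID in ids:
        label = "1"
    elif VICILIN_NTERM_ID in ids:
        label = "2"
    elif CUPIN1_ID in ids and ids & LEGUMIN_IDS:
        label = "3b"
    elif CUPIN1_ID in ids:
        label = "3a"
    else:
        label = "none"
    return DomainSetAssignment(entity_id=entity_id, set_label=label)


SCORE_NAMES = ("sum_A", "DHt", "sum_AE")
_SCORE_ATTR = {"sum_A": "sum_A", "DHt": "dht_percent", "sum_AE": "sum_AE"}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    score_name: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd < 0:
            raise ValidationError("GroupSummary: n < 1 or sd < 0")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    score_name: str
    distance: float
    p_value: float | None
    significant: bool | None


def _group_values(
    scores: ScoreTable,
    assignments: Sequence[DomainSetAssignment],
    score_name: str,
    merged: bool,
) -> dict[str, np.ndarray]:
    if score_name not in SCORE_NAMES:
        raise DomainError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")
    label_of = {
        a.entity_id: (a.merged_label if merged else a.set_label) for a in assignments
    }
    attr = _SCORE_ATTR[score_name]
    values: dict[str, list[float]] = {}
    all_values: list[float] = []
    for row in scores.rows:
        if row.entity_id not in label_of:
            raise DomainError(f"entity {row.entity_id} has no domain-set assignment")
        v = float(getattr(row, attr))
        all_values.append(v)
        label = label_of[row.entity_id]
        if label != "none":
            values.setdefault(label, []).append(v)
    out = {g: np.asarray(v) for g, v in sorted(values.items())}
    out["all"] = np.asarray(all_values)
    return out


def summarize_groups(
    scores: ScoreTable,
    assignments: Sequence[DomainSetAssignment],
    merged: bool = False,
) -> list[GroupSummary]:
    """Per-(group, score) mean and sample SD (n − 1 denominator).

    Groups are the domain-set labels, plus an "all" group containing
    every scored entity (including unclassified ones). Single-member
    groups report sd = 0. Empty groups are dropped with a warning.
    """
    summaries = []
    for score_name in SCORE_NAMES:
        groups = _group_values(scores, assignments, score_name, merged)
        for group, vals in groups.items():
            if len(vals) == 0:
                logger.warning("group %s has no members; excluded", group)
                continue
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            summaries.append(
                GroupSummary(
                    group=group,
                    score_name=score_name,
                    mean=float(np.mean(vals)),
                    sd=sd,
                    n=len(vals),
                )
            )
    return summaries


def pairwise_compare(
    scores: ScoreTable,
    assignments: Sequence[DomainSetAssignment],
    score_name: str,
    merged: bool = False,
) -> list[ComparisonResult]:
    """Compare every unordered pair of domain-set groups on one score.

    Distance is the absolute difference of group means (the Euclidean
    distance between scalar means). Groups with at least two members on
    both sides get a two-sided Welch t-test p-value and a significance
    flag at p < 0.05; smaller groups get the distance only.
    """
    groups = _group_values(scores, assignments, score_name, merged)
    groups.pop("all", None)
    results = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        va, vb = groups[ga], groups[gb]
        distance = abs(float(np.mean(va)) - float(np.mean(vb)))
        if len(va) >= 2 and len(vb) >= 2:
            stat = sps.ttest_ind(va, vb, equal_var=False)
            p = float(stat.pvalue)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if distance == 0 else 0.0
            results.append(
                ComparisonResult(ga, gb, score_name, distance, p, p < SIGNIFICANCE_LEVEL)
            )
        else:
            results.append(ComparisonResult(ga, gb, score_name, distance, None, None))
    return results


def distance_matrix(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of between-group distances."""
    labels = sorted({c.group_a for c in comparisons} | {c.group_b for c in comparisons})
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for c in comparisons:
        mat.loc[c.group_a, c.group_b] = c.distance
        mat.loc[c.group_b, c.group_a] = c.distance
    return mat


def bin_epitope_sumA(value: float) -> str:
    """Interval label for an epitope's ∑A, e.g. "1.6000-2.1000".

    The observed epitope range is divided into four fixed intervals with
    inclusive printed endpoints; values outside [0.1, 2.1] are labelled
    "out-of-range". Values are rounded to the printed 4-decimal
    precision before binning, so no value falls between intervals.
    """
    v = round(float(value), 4)
    if v < SUM_A_INTERVALS[0][0] or v > SUM_A_INTERVALS[-1][1]:
        return "out-of-range"
    for lo, hi in SUM_A_INTERVALS:
        if v <= hi:
            return f"{lo:.4f}-{hi:.4f}"
    raise AssertionError("unreachable")  # pragma: no cover
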