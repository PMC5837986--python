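"""Cohort-level statistics linking peri-ictal BNI to surgical outcome.

Four analyses: (i) Kruskal-Wallis comparison of pre-ictal, ictal and
post-ictal BNI pooled across the cohort; (ii) per-subject one-tailed
Mann-Whitney tests for elevated ictal BNI, required in both peri-ictal
epochs independently; (iii) a permutation chi-square test of the 2x2 table
elevated-ictal x surgical outcome (Engel I-II good vs III-IV poor) against
random reassignments of the elevated labels; (iv) ROC/AUC of DeltaBNI as an
outcome classifier, with AUC distributions from exhaustive half-group
splitting compared by a two-sided U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    InvalidInputError,
)
from .fc import mannwhitney_u

GOOD_ENGEL = ("I", "II")
POOR_ENGEL = ("III", "IV")


@dataclass
class CohortRecord:
    """Per-subject summary feeding the contingency and ROC statistics."""

    subject_id: str
    engel_class: str
    elevated_flags: tuple[bool, bool]
    delta_bni: float | None = None

    def __post_init__(self) -> None:
        if self.engel_class not in GOOD_ENGEL + POOR_ENGEL:
            raise InvalidInputError(f"unknown Engel class {self.engel_class!r}")

    @property
    def elevated_ictal(self) -> bool:
        """Elevated ictal BNI in both peri-ictal epochs independently."""
        return all(self.elevated_flags)

    @property
    def outcome_good(self) -> bool:
        return self.engel_class in GOOD_ENGEL


def kruskal_wallis_epochs(pre, ictal, post) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across the three epoch groups."""
    groups = [np.asarray(g, float) for g in (pre, ictal, post)]
    if any(g.size == 0 for g in groups):
        raise InsufficientDataError("each epoch group must be nonempty")
    if np.unique(np.concatenate(groups)).size < 2:
        raise InvalidInputError("all values identical; H is undefined")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def elevated_ictal_test(
    pre_values: np.ndarray, ictal_values: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float]:
    """One-tailed U test: is the ictal BNI median larger than the pre-ictal one?"""
    pre = np.asarray(pre_values, float)
    ict = np.asarray(ictal_values, float)
    if pre.size < 3 or ict.size < 3:
        raise InsufficientDataError("need >= 3 pre-ictal and >= 3 ictal BNI values")
    _, p = mannwhitney_u(ict, pre, alternative="greater")
    return p <= alpha, float(p)


def subject_elevated(epoch_results: list[tuple[bool, float]]) -> bool:
    """A subject shows elevated ictal BNI iff every epoch tested significant."""
    if not epoch_results:
        raise InsufficientDataError("no epoch results supplied")
    return all(flag for flag, _ in epoch_results)


def _chi_square_2x2(table: np.ndarray) -> float:
    """Plain Pearson chi-square (no continuity correction) of a 2x2 table."""
    table = np.asarray(table, float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n
    return float(np.sum((table - expected) ** 2 / expected))


def contingency_table(records: list[CohortRecord]) -> np.ndarray:
    """2x2 counts: rows elevated-ictal (yes/no), columns outcome (good/poor)."""
    t = np.zeros((2, 2), int)
    for r in records:
        t[0 if r.elevated_ictal else 1, 0 if r.outcome_good else 1] += 1
    return t


def permutation_chi_square(
    records: list[CohortRecord], n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the elevated-ictal x outcome association.

    The observed chi-square of the 2x2 table is compared against ``n_perm``
    random reassignments of the elevated labels (preserving their count);
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    good = np.array([r.outcome_good for r in records])
    elev = np.array([r.elevated_ictal for r in records])
    if good.sum() < 2 or (~good).sum() < 2:
        raise InsufficientDataError("need >= 2 subjects per outcome category")
    table = contingency_table(records)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(f"zero margin in table {table.tolist()}")
    observed = _chi_square_2x2(table)
    rng = np.random.default_rng(seed)
    n = len(records)
    count = 0
    for _ in range(n_perm):
        perm = elev[rng.permutation(n)]
        t = np.array(
            [
                [np.sum(perm & good), np.sum(perm & ~good)],
                [np.sum(~perm & good), np.sum(~perm & ~good)],
            ],
            float,
        )
        if _chi_square_2x2(t) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, float(p), table


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability P(score_pos > score_neg) + P(tie)/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both label classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def half_split_auc_compare(
    group_a: tuple[np.ndarray, np.ndarray], group_b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    """AUC distributions from exhaustive half-group splits, compared by U test.

    For each group, every subset of size floor(n/2) whose label composition
    still contains both classes yields one AUC; the two AUC distributions are
    compared two-sided.
    """
    dist_a = half_split_aucs(*group_a)
    dist_b = half_split_aucs(*group_b)
    _, p = mannwhitney_u(dist_a, dist_b, alternative="two-sided")
    return dist_a, dist_b, float(p)


def half_split_aucs(scores, labels) -> np.ndarray:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n = scores.size
    if n < 4 or labels.all() or not labels.any():
        raise InsufficientDataError("need >= 4 subjects with both classes present")
    k = n // 2
    aucs = []
    for idx in combinations(range(n), k):
        sub = list(idx)
        lab = labels[sub]
        if lab.all() or not lab.any():
            continue
        aucs.append(roc_auc(scores[sub], lab))
    if not aucs:
        raise InsufficientDataError("no half-split contains both classes")
    return np.array(aucs)
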