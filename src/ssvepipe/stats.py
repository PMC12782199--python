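"""AUC comparison and feature-count statistics.

DeLong's method treats the AUC as a two-sample U-statistic and derives its
variance from per-observation placement values: V10(i) for each positive is
the fraction of negatives it outranks (ties 1/2), V01(j) symmetrically for
negatives.  Then var(AUC) = var(V10)/m + var(V01)/n, and for two classifiers
scored on the same rows the covariance of the placement values gives the
paired variance of the AUC difference.  The unpaired variant simply adds the
two independent variances.

The retained-feature comparison between pathways is a Pearson χ² on the 2×2
table {retained, not retained} × {pathway}, with Yates continuity correction
by default.  Bonferroni correction is applied within hypothesis families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency, norm

from .classify import roc_auc

__all__ = [
    "ROCComparison",
    "TestFamily",
    "auc_variance",
    "delong_paired",
    "delong_unpaired",
    "chi_square_retained",
    "bonferroni_group",
]


@dataclass
class ROCComparison:
    delta_auc: float
    ci_low: float
    ci_high: float
    p_value: float
    variant: str  # "paired" | "unpaired"
    auc_a: float
    auc_b: float
    variance: float


@dataclass
class TestFamily:
    """A group of tests addressing one hypothesis, corrected together."""

    label: str
    p_values: tuple[float, ...]

    @property
    def m(self) -> int:
        return len(self.p_values)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values (V10 per positive, V01 per negative) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # pairwise comparison with ties counted 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single classifier."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01, auc = _placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def _z_test(delta: float, var: float) -> tuple[float, float, float]:
    if var <= 0:
        return 1.0 if delta == 0 else 0.0, delta, delta
    se = np.sqrt(var)
    z = delta / se
    p = float(2.0 * norm.sf(abs(z)))
    half = norm.ppf(0.975) * se
    return p, float(np.clip(delta - half, -1.0, 1.0)), float(np.clip(delta + half, -1.0, 1.0))


def delong_paired(scores_a, scores_b, labels) -> ROCComparison:
    """Compare two classifiers scored on the same rows (correlated AUCs)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired comparison needs equal-length score and label vectors")
    va10, va01, auc_a = _placements(scores_a, labels)
    vb10, vb01, auc_b = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    p, lo, hi = _z_test(delta, var)
    return ROCComparison(delta, lo, hi, p, "paired", auc_a, auc_b, float(var))


def delong_unpaired(scores_a, labels_a, scores_b, labels_b) -> ROCComparison:
    """Compare classifiers scored on independent samples (no covariance term)."""
    auc_a, var_a = auc_variance(scores_a, labels_a)
    auc_b, var_b = auc_variance(scores_b, labels_b)
    delta = auc_a - auc_b
    var = var_a + var_b
    p, lo, hi = _z_test(delta, var)
    return ROCComparison(delta, lo, hi, p, "unpaired", auc_a, auc_b, float(var))


def chi_square_retained(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Pearson χ²(1) on the 2×2 retained/not × pathway table.

    Yates continuity correction is on by default.  Returns (statistic, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise ValueError("need 0 ≤ k ≤ n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("χ² table has a zero margin")
    if k1 == k2 and n1 == n2:
        return 0.0, 1.0
    res = chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def bonferroni_group(families: list[TestFamily]) -> list[tuple[str, tuple[float, ...]]]:
    """Within-family Bonferroni: adjusted p = min(1, p·m) per family member."""
    if not families:
        raise ValueError("no test families supplied")
    out = []
    for fam in families:
        if fam.m < 1:
            raise ValueError(f"family {fam.label!r} is empty")
        if any(not (0.0 <= p <= 1.0) for p in fam.p_values):
            raise ValueError(f"family {fam.label!r} has a p-value outside [0, 1]")
        out.append((fam.label, tuple(min(1.0, p * fam.m) for p in fam.p_values)))
    return out
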