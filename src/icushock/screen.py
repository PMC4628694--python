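"""Survivor/nonsurvivor univariate screening with FDR control.

Each feature is compared between groups with the two-sided Wilcoxon
rank-sum test (exact enumeration for small tie-free groups, normal
approximation with tie correction otherwise) and Benjamini-Hochberg
q-values are attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import NONSURVIVOR, SURVIVOR, CohortMatrix

ALPHA = 0.05
_EXACT_MAX_N = 10


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    median_S: float
    q25_S: float
    q75_S: float
    median_NS: float
    q25_NS: float
    q75_NS: float
    p_value: float
    q_value: float
    significant: bool


def rank_sum_test(values_S: np.ndarray, values_NS: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both groups have at most 10
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction.  Degenerate pooled samples (all
    values identical) give p = 1.
    """
    x = np.asarray(values_S, dtype=float)
    y = np.asarray(values_NS, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(min(res.pvalue, 1.0))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(matrix: CohortMatrix, alpha: float = ALPHA) -> list[UnivariateResult]:
    """Rank-sum test of every feature between S and NS, with BH q-values.

    Results follow the canonical feature order (variable-major); a feature
    is significant when its raw p-value is below ``alpha``.
    """
    labels = np.asarray(matrix.labels)
    is_s = labels == SURVIVOR
    is_ns = labels == NONSURVIVOR
    if not is_s.any() or not is_ns.any():
        raise ValueError("both S and NS labels must be present")
    p_values = np.empty(len(matrix.feature_names))
    quartiles = []
    for j, _name in enumerate(matrix.feature_names):
        col = matrix.X[:, j]
        xs, ys = col[is_s], col[is_ns]
        p_values[j] = rank_sum_test(xs, ys)
        quartiles.append((
            np.median(xs), *np.percentile(xs, [25, 75]),
            np.median(ys), *np.percentile(ys, [25, 75]),
        ))
    q_values = fdr_adjust(p_values)
    return [
        UnivariateResult(
            feature=name,
            median_S=float(q[0]), q25_S=float(q[1]), q75_S=float(q[2]),
            median_NS=float(q[3]), q25_NS=float(q[4]), q75_NS=float(q[5]),
            p_value=float(p), q_value=float(qv),
            significant=bool(p < alpha),
        )
        for name, q, p, qv in zip(matrix.feature_names, quartiles,
                                  p_values, q_values)
    ]
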