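"""Diagnostic-accuracy evaluation and group comparison.

Cross-tabulates predicted residual/non-residual calls against the reference
response labels (positive class = non-complete response, i.e. residual
disease), derives sensitivity / specificity / PPV / NPV / accuracy with
exact Clopper–Pearson 95% intervals, and compares relative-enhancement
values between groups with the Wilcoxon rank-sum test (exact by enumeration
for small samples).

The Clopper–Pearson choice is verifiable against the printed sensitivity,
specificity and accuracy intervals of the reference cross-tabulation; the
interval method is therefore labelled explicitly in every summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .response import ResponseCall

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "RankSumResult",
    "cross_tabulate",
    "clopper_pearson",
    "diagnostic_metrics",
    "wilcoxon_rank_sum",
]

#: labels counted as the positive reference class (non-complete response)
POSITIVE_LABELS = {"PR", "SD", "non_complete", "non_complete_response", "residual"}
NEGATIVE_LABELS = {"CR", "complete", "complete_response", "non_residual"}

#: p < 0.05 is reported as significant (a flag, never a filter)
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ConfusionTable:
    """2×2 counts: prediction (residual / non-residual) vs reference response."""

    tp: int  # residual predicted, non-complete response
    fp: int  # residual predicted, complete response
    fn: int  # non-residual predicted, non-complete response
    tn: int  # non-residual predicted, complete response

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricCI:
    point: float | None
    lo: float | None
    hi: float | None
    successes: int
    n: int


@dataclass
class DiagnosticSummary:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    accuracy: MetricCI
    alpha: float
    ci_method: str = "clopper_pearson_exact"

    def as_dict(self) -> dict:
        out = {"alpha": self.alpha, "ci_method": self.ci_method}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricCI = getattr(self, name)
            out[name] = {
                "value": m.point, "ci_lo": m.lo, "ci_hi": m.hi,
                "successes": m.successes, "n": m.n,
            }
        return out


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    method: Literal["exact", "normal_approximation"]
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def _as_prediction(p) -> str:
    if isinstance(p, ResponseCall):
        return p.call
    p = str(p)
    if p not in ("residual", "non_residual"):
        raise ValueError(f"unknown prediction label {p!r}")
    return p


def _is_positive_reference(label: str) -> bool:
    if label in POSITIVE_LABELS:
        return True
    if label in NEGATIVE_LABELS:
        return False
    raise ValueError(f"unknown reference label {label!r}")


def cross_tabulate(
    predictions: Sequence[ResponseCall | str],
    references: Sequence[str],
) -> ConfusionTable:
    """Count predicted vs reference response (order-invariant).

    References may be mRECIST categories (``CR``/``PR``/``SD``; PR and SD
    collapse to non-complete response) or explicit
    ``complete``/``non_complete`` labels.
    """
    if len(predictions) != len(references):
        raise ValueError("predictions and references differ in length")
    if len(predictions) == 0:
        raise ValueError("empty input")
    tp = fp = fn = tn = 0
    for p, r in zip(predictions, references):
        pred_residual = _as_prediction(p) == "residual"
        ref_positive = _is_positive_reference(str(r))
        if pred_residual and ref_positive:
            tp += 1
        elif pred_residual:
            fp += 1
        elif ref_positive:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta-distribution quantiles.

    ``lo = 0`` exactly when ``successes = 0`` and ``hi = 1`` exactly when
    ``successes = n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError("successes must be in [0, n]")
    k = int(successes)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def _metric(successes: int, n: int, alpha: float) -> MetricCI:
    if n == 0:
        return MetricCI(point=None, lo=None, hi=None, successes=successes, n=0)
    lo, hi = clopper_pearson(successes, n, alpha)
    return MetricCI(point=successes / n, lo=lo, hi=hi, successes=successes, n=n)


def diagnostic_metrics(table: ConfusionTable, alpha: float = 0.05) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    Metrics with a zero denominator are reported as undefined (None); the
    others are still computed.
    """
    return DiagnosticSummary(
        sensitivity=_metric(table.tp, table.tp + table.fn, alpha),
        specificity=_metric(table.tn, table.tn + table.fp, alpha),
        ppv=_metric(table.tp, table.tp + table.fp, alpha),
        npv=_metric(table.tn, table.tn + table.fn, alpha),
        accuracy=_metric(table.tp + table.tn, table.total, alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

EXACT_MAX_N = 20


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    For total sample size ≤ 20 the p-value is exact: all C(n, n_a)
    assignments of the pooled mid-ranks are enumerated and the two-sided
    tail is the fraction of assignments whose rank sum deviates from its
    mean at least as much as the observed one (this handles ties by
    enumerating over the observed mid-ranks). Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())
    mean_w = n_a * (n + 1) / 2.0

    if n <= EXACT_MAX_N:
        dev_obs = abs(w_obs - mean_w)
        total = comb(n, n_a)
        hits = 0
        for combo in combinations(range(n), n_a):
            w = ranks[list(combo)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
        return RankSumResult(statistic=w_obs, p_value=float(min(p, 1.0)),
                             method="exact", n_a=n_a, n_b=n_b)

    # normal approximation with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return RankSumResult(statistic=w_obs, p_value=1.0,
                             method="normal_approximation", n_a=n_a, n_b=n_b)
    z = (w_obs - mean_w) / np.sqrt(var_w)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RankSumResult(statistic=w_obs, p_value=min(p, 1.0),
                         method="normal_approximation", n_a=n_a, n_b=n_b)
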