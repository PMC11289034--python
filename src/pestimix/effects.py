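"""Bootstrapped effect sizes: unpaired mean differences vs a reference arm,
gradual-vs-abrupt rate contrasts, and an ordinary-least-squares richness
trend with a case-resampling bootstrap CI.

The point estimate is always the exact difference of sample means (or the
exact OLS slope); only the confidence interval is bootstrap-based, via
stratified resampling with replacement within each group. CI methods:
bias-corrected-and-accelerated (default) or plain percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

CI_METHODS = ("bca", "percentile")
_SCIPY_METHOD = {"bca": "BCa", "percentile": "percentile"}


class EstimationError(ValueError):
    """Invalid inputs to an effect-size estimator."""


@dataclass(frozen=True)
class EffectEstimate:
    """Unpaired mean difference (treatment - reference) with a 95% CI."""

    response: str
    arm: str
    reference: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_method: str
    seed: int | None


@dataclass(frozen=True)
class TrendEstimate:
    """OLS slope of a response on pesticide richness with a 95% bootstrap CI."""

    response: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None


def _check_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise EstimationError(f"{name} group needs >= 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise EstimationError(f"{name} group contains non-finite values")
    return arr


def bootstrap_mean_difference(
    treat: Sequence[float],
    ref: Sequence[float],
    n_boot: int = 5000,
    ci_method: str = "bca",
    seed: int | None = None,
    *,
    response: str = "",
    arm: str = "",
    reference: str = "",
    confidence_level: float = 0.95,
) -> EffectEstimate:
    """Unpaired mean difference mean(treat) - mean(ref) with a bootstrap CI.

    Groups are resampled independently with replacement, sizes preserved.
    Deterministic given `seed`; the point estimate never depends on the
    bootstrap.
    """
    if ci_method not in CI_METHODS:
        raise EstimationError(f"ci_method must be one of {CI_METHODS}")
    t = _check_group(treat, "treatment")
    r = _check_group(ref, "reference")
    point = float(t.mean() - r.mean())
    if np.ptp(t) == 0 and np.ptp(r) == 0:
        # degenerate constant groups: the bootstrap distribution is a point mass
        lo = hi = point
    else:
        res = stats.bootstrap(
            (t, r),
            lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
            n_resamples=n_boot,
            vectorized=True,
            paired=False,
            confidence_level=confidence_level,
            method=_SCIPY_METHOD[ci_method],
            rng=np.random.default_rng(seed),
        )
        lo = float(res.confidence_interval.low)
        hi = float(res.confidence_interval.high)
    return EffectEstimate(
        response=response, arm=arm, reference=reference,
        estimate=point, ci_low=lo, ci_high=hi,
        n_boot=n_boot, ci_method=ci_method, seed=seed,
    )


def paired_rate_contrast(
    gradual: Sequence[float],
    abrupt: Sequence[float],
    n_boot: int = 5000,
    ci_method: str = "bca",
    seed: int | None = None,
    *,
    response: str = "",
    arm: str = "",
) -> EffectEstimate:
    """Gradual-minus-abrupt contrast for one treatment level.

    Arms are paired at the treatment level (same richness, different
    application rate), not at the unit level, so this is an unpaired
    bootstrap mean difference with gradual as the treatment group.
    """
    return bootstrap_mean_difference(
        gradual, abrupt, n_boot=n_boot, ci_method=ci_method, seed=seed,
        response=response, arm=arm, reference="abrupt",
    )


def richness_trend(
    richness: Sequence[float],
    values: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    response: str = "",
) -> TrendEstimate:
    """OLS slope of a response on pesticide richness (0/1/5/10).

    The CI is a case-resampling percentile bootstrap over (richness, value)
    pairs; resamples that collapse to a single richness level are redrawn.
    """
    x = np.asarray(richness, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EstimationError("richness and values must be equal-length 1-D")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise EstimationError("richness trend requires finite inputs")
    if np.unique(x).size < 2:
        raise EstimationError("need >= 2 distinct richness levels")
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(x[idx]).size >= 2:
                break
        boots[b] = np.polyfit(x[idx], y[idx], 1)[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return TrendEstimate(
        response=response, slope=float(slope), intercept=float(intercept),
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed,
    )
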