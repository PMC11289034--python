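"""Multi-stressor null models: additive, multiplicative, and dominative
predictions of joint pesticide effects from single-pesticide data, with
nonparametric bootstrap CIs and a synergism/antagonism classification.

Single effects are absolute mean differences from control, d_i = mean_i -
mu_c, on the response scale. With composition S:

    additive        sum_{i in S} d_i
    multiplicative  mu_c * prod_{i in S} (1 + d_i / mu_c) - mu_c
    dominative      the d_i of maximal |d_i| (sign preserved; ties broken
                    by catalogue order, i.e. the first code supplied)

All three coincide on singletons. Bootstrap CIs resample the control and
every involved single-pesticide arm with replacement (1000 iterations by
default), recomputing mu_c, the d_i, and the model prediction per
iteration; CIs are the 2.5/97.5 percentiles. The interaction call compares
the observed mixture effect with the prediction through the joint bootstrap
distribution of their difference delta = observed - predicted: the verdict
is synergistic when delta's CI excludes zero and the deviation points in
the direction of the observed joint effect (the mixture is more extreme
than the null model allows — including the canonical case of a negative
joint effect where singles predict a neutral-to-positive one),
antagonistic when the CI excludes zero in the damping direction, and
consistent otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .design import TreatmentArm
from .effects import EffectEstimate

logger = logging.getLogger("pestimix")

MODELS = ("additive", "multiplicative", "dominative")
VERDICTS = ("synergistic", "antagonistic", "consistent")


class NullModelError(ValueError):
    """Invalid inputs to a null-model computation."""


@dataclass(frozen=True)
class SingleEffectSet:
    """Control mean and per-pesticide mean differences for one response.

    The insertion order of `d` is the catalogue order used for the
    dominative tie-break.
    """

    response: str
    mu_c: float
    d: dict[str, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_c):
            raise NullModelError("control mean must be finite")

    @classmethod
    def from_groups(
        cls,
        control: Sequence[float],
        singles: Mapping[str, Sequence[float]],
        response: str = "",
    ) -> "SingleEffectSet":
        mu_c = float(np.mean(control))
        return cls(
            response=response,
            mu_c=mu_c,
            d={c: float(np.mean(v)) - mu_c for c, v in singles.items()},
        )

    def subset(self, composition: Iterable[str]) -> np.ndarray:
        comp = tuple(composition)
        missing = [c for c in comp if c not in self.d]
        if missing:
            raise NullModelError(f"no single effect for codes {missing}")
        # keep catalogue order so argmax tie-breaks deterministically
        return np.array([self.d[c] for c in self.d if c in set(comp)])


def predict_additive(effects: SingleEffectSet, composition: Iterable[str]) -> float:
    """Sum of single mean differences over the composition."""
    return float(effects.subset(composition).sum())


def predict_multiplicative(effects: SingleEffectSet, composition: Iterable[str]) -> float:
    """Joint effect from compounding proportional changes of the control mean."""
    if effects.mu_c == 0:
        raise NullModelError("multiplicative model undefined for zero control mean")
    d = effects.subset(composition)
    factors = 1.0 + d / effects.mu_c
    if np.any(factors < 0):
        logger.info(
            "multiplicative model: %d factor(s) imply a response sign flip",
            int(np.sum(factors < 0)),
        )
    return float(effects.mu_c * np.prod(factors) - effects.mu_c)


def predict_dominative(effects: SingleEffectSet, composition: Iterable[str]) -> float:
    """The single mean difference of largest magnitude, sign preserved.

    Ties in |d| go to the pesticide earliest in catalogue order.
    """
    d = effects.subset(composition)
    if d.size == 0:
        raise NullModelError("dominative model requires a non-empty composition")
    return float(d[np.argmax(np.abs(d))])


_PREDICTORS = {
    "additive": predict_additive,
    "multiplicative": predict_multiplicative,
    "dominative": predict_dominative,
}


def predict(model: str, effects: SingleEffectSet, composition: Iterable[str]) -> float:
    if model not in MODELS:
        raise NullModelError(f"unknown null model {model!r}")
    return _PREDICTORS[model](effects, composition)


@dataclass(frozen=True)
class NullPrediction:
    """A null model's predicted joint effect with a percentile bootstrap CI."""

    model: str
    compositions: tuple[tuple[str, ...], ...]
    predicted: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_redrawn: int = 0
    per_composition: dict[tuple[str, ...], float] = field(default_factory=dict)


@dataclass(frozen=True)
class InteractionCall:
    """Observed-vs-predicted comparison for one mixture arm and model."""

    model: str
    observed: EffectEstimate
    prediction: NullPrediction
    delta: float
    delta_ci_low: float
    delta_ci_high: float
    verdict: str


def _as_composition_list(
    compositions: Iterable[str] | Iterable[Iterable[str]],
) -> list[tuple[str, ...]]:
    comps = list(compositions)
    if not comps:
        raise NullModelError("at least one composition is required")
    if all(isinstance(c, str) for c in comps):
        return [tuple(comps)]  # a single composition given flat
    return [tuple(c) for c in comps]


def _check_groups(
    singles: Mapping[str, Sequence[float]],
    control: Sequence[float],
    comps: Sequence[tuple[str, ...]],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    ctrl = np.asarray(control, dtype=float)
    if ctrl.size < 2 or not np.all(np.isfinite(ctrl)):
        raise NullModelError("control needs >= 2 finite replicates")
    needed = {c for comp in comps for c in comp}
    missing = needed - set(singles)
    if missing:
        raise NullModelError(f"single-arm data missing for codes {sorted(missing)}")
    arrs = {}
    for code in singles:  # keep catalogue order
        a = np.asarray(singles[code], dtype=float)
        if a.size < 2 or not np.all(np.isfinite(a)):
            raise NullModelError(f"single arm {code!r} needs >= 2 finite replicates")
        arrs[code] = a
    return arrs, ctrl


def _boot_means(x: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    return x[idx].mean(axis=1)


def _model_matrix(
    model: str,
    mu_c: np.ndarray,
    D: np.ndarray,
) -> np.ndarray:
    """Vectorized prediction over bootstrap iterations.

    mu_c: (n_boot,), D: (n_boot, k) single mean differences in catalogue
    order for one composition.
    """
    if model == "additive":
        return D.sum(axis=1)
    if model == "multiplicative":
        return mu_c * np.prod(1.0 + D / mu_c[:, None], axis=1) - mu_c
    # dominative: argmax of |d|; np.argmax takes the first maximum, which is
    # the catalogue-order tie-break
    rows = np.arange(D.shape[0])
    return D[rows, np.argmax(np.abs(D), axis=1)]


def _bootstrap_machinery(
    singles: Mapping[str, Sequence[float]],
    control: Sequence[float],
    model: str,
    comps: Sequence[tuple[str, ...]],
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], int]:
    """Shared bootstrap core: per-iteration control means, predictions.

    Returns (mu_c_boot, pred_boot, single_mean_boot, n_redrawn). Within one
    iteration the same control resample feeds every d_i (and, in
    classify_interaction, the observed effect), emulating a coherent
    re-run of the whole experiment.
    """
    arrs, ctrl = _check_groups(singles, control, comps)
    if model not in MODELS:
        raise NullModelError(f"unknown null model {model!r}")
    mu_c_b = _boot_means(ctrl, n_boot, rng)
    means_b = {c: _boot_means(a, n_boot, rng) for c, a in arrs.items()}
    n_redrawn = 0
    if model == "multiplicative":
        # resampled zero control means make the proportional model undefined
        bad = mu_c_b == 0.0
        while np.any(bad):
            n_redrawn += int(bad.sum())
            mu_c_b[bad] = _boot_means(ctrl, int(bad.sum()), rng)
            bad = mu_c_b == 0.0
        if n_redrawn:
            logger.info("redrew %d iterations with zero control mean", n_redrawn)
    preds = np.zeros(n_boot)
    codes_in_order = list(arrs)
    for comp in comps:
        cols = [c for c in codes_in_order if c in set(comp)]
        D = np.column_stack([means_b[c] - mu_c_b for c in cols])
        preds += _model_matrix(model, mu_c_b, D)
    preds /= len(comps)
    return mu_c_b, preds, means_b, n_redrawn


def bootstrap_prediction(
    singles: Mapping[str, Sequence[float]],
    control: Sequence[float],
    model: str,
    compositions: Iterable[str] | Iterable[Iterable[str]],
    n_boot: int = 1000,
    seed: int | None = None,
) -> NullPrediction:
    """Null-model prediction with a nonparametric bootstrap percentile CI.

    `compositions` may be a single composition (iterable of codes) or a list
    of per-replicate compositions, in which case the prediction is the
    replicate-weighted average over compositions (computed inside every
    bootstrap iteration). The point prediction uses unresampled means.
    """
    if n_boot < 1:
        raise NullModelError("n_boot must be >= 1")
    comps = _as_composition_list(compositions)
    rng = np.random.default_rng(seed)
    _, preds, _, n_redrawn = _bootstrap_machinery(
        singles, control, model, comps, n_boot, rng
    )
    eff = SingleEffectSet.from_groups(control, singles)
    per_comp = {comp: predict(model, eff, comp) for comp in dict.fromkeys(comps)}
    point = float(np.mean([per_comp[c] for c in comps]))
    lo, hi = np.percentile(preds, [2.5, 97.5])
    return NullPrediction(
        model=model,
        compositions=tuple(comps),
        predicted=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
        per_composition=per_comp,
    )


def mixture_prediction_for_arm(
    arm: TreatmentArm,
    singles: Mapping[str, Sequence[float]],
    control: Sequence[float],
    model: str,
    n_boot: int = 1000,
    seed: int | None = None,
    expected_subset: bool = False,
) -> NullPrediction:
    """Replicate-composition-averaged prediction for a mixture arm.

    By default uses the arm's realized per-replicate compositions. With
    ``expected_subset=True`` the prediction instead averages over every
    size-`richness` subset of the supplied single-arm codes (the
    expectation under random subset assignment).
    """
    if arm.richness < 2:
        raise NullModelError("mixture predictions require arm richness >= 2")
    if expected_subset:
        from itertools import combinations

        comps: list[tuple[str, ...]] = [
            tuple(c) for c in combinations(list(singles), arm.richness)
        ]
    else:
        comps = arm.compositions
    return bootstrap_prediction(
        singles, control, model, comps, n_boot=n_boot, seed=seed
    )


def _verdict(delta_lo: float, delta_hi: float, observed: float, predicted: float) -> str:
    """Three-way interaction verdict from the delta CI and point values.

    Synergistic: the deviation from the prediction points in the direction
    of the observed joint effect (the mixture pushed the response further
    than the null model allows, e.g. an observed negative joint effect
    below a neutral-to-positive prediction). Antagonistic: the deviation
    pulls the joint effect back toward, or past, zero relative to the
    prediction. Consistent: the delta CI covers zero.
    """
    if delta_lo <= 0.0 <= delta_hi:
        return "consistent"
    delta = observed - predicted
    direction = observed if observed != 0.0 else -delta
    return "synergistic" if delta * direction > 0 else "antagonistic"


def classify_interaction(
    mixture: Sequence[float],
    control: Sequence[float],
    singles: Mapping[str, Sequence[float]],
    model: str,
    compositions: Iterable[str] | Iterable[Iterable[str]] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    response: str = "",
    arm: str = "",
) -> InteractionCall:
    """Observed-vs-predicted interaction call for one mixture arm.

    Each bootstrap iteration resamples the mixture arm, the control, and
    every single-pesticide arm, then forms delta = (mixture mean - control
    mean) - model prediction; the verdict derives from delta's 95%
    percentile CI (see module docstring). Point values use unresampled
    means. Deterministic given `seed`.
    """
    mix = np.asarray(mixture, dtype=float)
    if mix.size < 2 or not np.all(np.isfinite(mix)):
        raise NullModelError("mixture arm needs >= 2 finite replicates")
    comps = _as_composition_list(compositions if compositions is not None else list(singles))
    rng = np.random.default_rng(seed)
    mu_c_b, preds_b, _, n_redrawn = _bootstrap_machinery(
        singles, control, model, comps, n_boot, rng
    )
    mix_b = _boot_means(mix, n_boot, rng)
    delta_b = (mix_b - mu_c_b) - preds_b

    eff = SingleEffectSet.from_groups(control, singles, response=response)
    per_comp = {comp: predict(model, eff, comp) for comp in dict.fromkeys(comps)}
    predicted = float(np.mean([per_comp[c] for c in comps]))
    observed = float(mix.mean()) - eff.mu_c
    delta = observed - predicted
    if np.ptp(delta_b) == 0:
        d_lo = d_hi = float(delta_b[0]) if delta_b.size else delta
    else:
        d_lo, d_hi = (float(v) for v in np.percentile(delta_b, [2.5, 97.5]))
    p_lo, p_hi = (float(v) for v in np.percentile(preds_b, [2.5, 97.5]))
    obs_lo, obs_hi = (float(v) for v in np.percentile(mix_b - mu_c_b, [2.5, 97.5]))

    return InteractionCall(
        model=model,
        observed=EffectEstimate(
            response=response, arm=arm, reference="control",
            estimate=observed, ci_low=obs_lo, ci_high=obs_hi,
            n_boot=n_boot, ci_method="percentile", seed=seed,
        ),
        prediction=NullPrediction(
            model=model, compositions=tuple(comps), predicted=predicted,
            ci_low=p_lo, ci_high=p_hi, n_boot=n_boot, seed=seed,
            n_redrawn=n_redrawn, per_composition=per_comp,
        ),
        delta=delta,
        delta_ci_low=d_lo,
        delta_ci_high=d_hi,
        verdict=_verdict(d_lo, d_hi, observed, predicted),
    )
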