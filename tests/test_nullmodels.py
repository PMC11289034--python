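import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    exhaustive_additive_prediction_distribution,
    quantile_bracket_check,
)
from pestimix import (
    NullModelError,
    SingleEffectSet,
    TreatmentArm,
    bootstrap_prediction,
    classify_interaction,
    mixture_prediction_for_arm,
    predict_additive,
    predict_dominative,
    predict_multiplicative,
)


def _effects(mu_c=10.0, **d):
    return SingleEffectSet(response="EC", mu_c=mu_c, d=dict(d))


def test_additive_hand_values():
    eff = _effects(A=1.0, B=2.0)
    assert predict_additive(eff, ("A",)) == 1.0
    assert predict_additive(eff, ("A", "B")) == 3.0
    assert predict_additive(_effects(A=0.0, B=0.0), ("A", "B")) == 0.0


def test_multiplicative_hand_values():
    eff = _effects(mu_c=10.0, A=1.0, B=2.0)  # +10% and +20%
    assert predict_multiplicative(eff, ("A", "B")) == pytest.approx(3.2)
    assert predict_multiplicative(eff, ("A",)) == pytest.approx(1.0)
    assert predict_multiplicative(_effects(A=0.0, B=0.0), ("A", "B")) == pytest.approx(0.0)


def test_dominative_hand_values():
    eff = _effects(A=1.0, B=-2.0, C=0.5)
    assert predict_dominative(eff, ("A", "B", "C")) == -2.0
    assert predict_dominative(eff, ("C",)) == 0.5


def test_dominative_tie_break_catalogue_order():
    # |+2| ties |-2|: the pesticide earliest in catalogue order wins
    eff = _effects(A=2.0, B=-2.0)
    assert predict_dominative(eff, ("A", "B")) == 2.0
    assert predict_dominative(eff, ("B", "A")) == 2.0  # order of d, not composition
    eff2 = _effects(B=-2.0, A=2.0)  # insertion order reversed
    assert predict_dominative(eff2, ("A", "B")) == -2.0


@settings(max_examples=200, deadline=None)
@given(
    d=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
    mu=st.floats(1.0, 20.0),
)
def test_dominative_matches_brute_force_scan(d, mu):
    codes = [f"P{i}" for i in range(len(d))]
    eff = SingleEffectSet(response="x", mu_c=mu, d=dict(zip(codes, d)))
    got = predict_dominative(eff, codes)
    best = max(d, key=abs)  # same first-max tie-break as the model
    assert got == best


@settings(max_examples=200, deadline=None)
@given(
    props=st.lists(st.floats(-0.01, 0.01), min_size=1, max_size=10),
    mu=st.floats(0.5, 100.0),
)
def test_additive_multiplicative_first_order_agreement(props, mu):
    codes = [f"P{i}" for i in range(len(props))]
    eff = SingleEffectSet(response="x", mu_c=mu, d={c: p * mu for c, p in zip(codes, props)})
    add = predict_additive(eff, codes)
    mult = predict_multiplicative(eff, codes)
    bound = (sum(abs(p) for p in props)) ** 2 * mu
    assert abs(add - mult) <= bound + 1e-12


@settings(max_examples=100, deadline=None)
@given(d=st.floats(-3, 3), mu=st.floats(0.5, 50.0))
def test_all_models_coincide_on_singletons(d, mu):
    eff = SingleEffectSet(response="x", mu_c=mu, d={"A": d})
    assert predict_additive(eff, ("A",)) == pytest.approx(d)
    assert predict_multiplicative(eff, ("A",)) == pytest.approx(d)
    assert predict_dominative(eff, ("A",)) == pytest.approx(d)


def test_prediction_errors():
    eff = _effects(A=1.0)
    with pytest.raises(NullModelError):
        predict_additive(eff, ("A", "Z"))
    with pytest.raises(NullModelError):
        predict_dominative(eff, ())
    with pytest.raises(NullModelError):
        predict_multiplicative(_effects(mu_c=0.0, A=1.0), ("A",))


def test_zero_variance_bootstrap_prediction_equals_closed_form():
    ctrl = [10.0, 10.0, 10.0]
    singles = {"A": [11.0, 11.0], "B": [12.0, 12.0]}
    for model, want in (("additive", 3.0), ("multiplicative", 3.2), ("dominative", 2.0)):
        pred = bootstrap_prediction(singles, ctrl, model, ("A", "B"), n_boot=200, seed=0)
        assert pred.predicted == pytest.approx(want)
        assert pred.ci_low == pred.ci_high == pytest.approx(want)


def test_bootstrap_point_prediction_invariant_to_seed(rng):
    ctrl = rng.normal(10, 1, 10)
    singles = {c: rng.normal(11, 1, 5) for c in "AB"}
    p1 = bootstrap_prediction(singles, ctrl, "additive", ("A", "B"), n_boot=300, seed=1)
    p2 = bootstrap_prediction(singles, ctrl, "additive", ("A", "B"), n_boot=600, seed=2)
    assert p1.predicted == p2.predicted
    assert (p1.ci_low, p1.ci_high) != (p2.ci_low, p2.ci_high)


def test_full_set_additive_prediction_is_sum_of_point_effects(rng):
    codes = [f"P{i}" for i in range(10)]
    ctrl = rng.normal(10, 1, 20)
    singles = {c: rng.normal(10.5, 1, 5) for c in codes}
    pred = bootstrap_prediction(singles, ctrl, "additive", codes, n_boot=100, seed=0)
    d_sum = sum(np.mean(v) - ctrl.mean() for v in singles.values())
    assert pred.predicted == pytest.approx(d_sum)


def test_bootstrap_ci_endpoints_match_exhaustive_enumeration(rng):
    # groups of size <= 3: the percentile endpoints of a large bootstrap must
    # approach the percentiles of the exhaustively enumerated resample
    # distribution
    ctrl = np.array([9.0, 10.0, 11.5])
    singles = {"A": np.array([10.0, 12.0]), "B": np.array([8.0, 9.5, 13.0])}
    exact = exhaustive_additive_prediction_distribution(ctrl, singles)
    pred = bootstrap_prediction(singles, ctrl, "additive", ("A", "B"),
                                n_boot=40_000, seed=4)
    assert quantile_bracket_check(exact, pred.ci_low, 0.025)
    assert quantile_bracket_check(exact, pred.ci_high, 0.975)


def _arm(comps):
    return TreatmentArm(
        arm_id="mix", rate="abrupt", richness=len(comps[0]),
        composition_per_replicate=dict(enumerate(comps)), n_replicates=len(comps),
    )


def test_mixture_prediction_single_composition_identity():
    ctrl = [10.0, 10.0]
    singles = {"A": [10.5, 10.5], "B": [10.5, 10.5]}
    arm = _arm([("A", "B")] * 4)
    pred = mixture_prediction_for_arm(arm, singles, ctrl, "additive", n_boot=100, seed=0)
    direct = bootstrap_prediction(singles, ctrl, "additive", ("A", "B"), n_boot=100, seed=0)
    assert pred.predicted == direct.predicted
    assert pred.per_composition == {("A", "B"): 1.0}


def test_mixture_prediction_averages_compositions():
    # two compositions with point predictions 1 and 3, equal replicate counts
    ctrl = [10.0, 10.0]
    singles = {
        "A": [10.5, 10.5], "B": [10.5, 10.5],
        "C": [11.5, 11.5], "D": [11.5, 11.5],
    }
    arm = _arm([("A", "B"), ("C", "D")])
    pred = mixture_prediction_for_arm(arm, singles, ctrl, "additive", n_boot=100, seed=0)
    assert pred.per_composition[("A", "B")] == pytest.approx(1.0)
    assert pred.per_composition[("C", "D")] == pytest.approx(3.0)
    assert pred.predicted == pytest.approx(2.0)


def test_expected_subset_mode_averages_all_subsets():
    ctrl = [10.0, 10.0]
    singles = {"A": [11.0, 11.0], "B": [12.0, 12.0], "C": [13.0, 13.0]}
    arm = _arm([("A", "B")])
    pred = mixture_prediction_for_arm(
        arm, singles, ctrl, "additive", n_boot=50, seed=0, expected_subset=True
    )
    # subsets AB, AC, BC -> predictions 3, 4, 5 -> mean 4
    assert len(pred.per_composition) == 3
    assert pred.predicted == pytest.approx(4.0)


def test_mixture_prediction_requires_richness_two():
    arm = TreatmentArm("one", "abrupt", 1, {0: ("A",)}, 1)
    with pytest.raises(NullModelError):
        mixture_prediction_for_arm(arm, {"A": [1.0, 2.0]}, [0.0, 1.0], "additive")


def test_classify_zero_variance_exact_match_is_consistent():
    ctrl = [10.0, 10.0]
    singles = {"A": [11.0, 11.0], "B": [12.0, 12.0]}
    mix = [13.0, 13.0]  # exactly the additive prediction 3 above mu_c
    call = classify_interaction(mix, ctrl, singles, "additive", n_boot=100, seed=0)
    assert call.verdict == "consistent"
    assert call.delta == pytest.approx(0.0)


def test_classify_detects_synergism_and_antagonism(rng):
    ctrl = rng.normal(10, 0.2, 20)
    singles = {c: rng.normal(10.5, 0.2, 10) for c in "AB"}
    # additive prediction ~ +1; observed ~ -2: more extreme along its own
    # (negative) direction -> synergistic
    syn = classify_interaction(rng.normal(8, 0.2, 20), ctrl, singles,
                               "additive", n_boot=500, seed=1)
    assert syn.verdict == "synergistic"
    # observed ~ +0.3, prediction ~ +1: damped -> antagonistic
    ant = classify_interaction(rng.normal(10.3, 0.2, 20), ctrl, singles,
                               "additive", n_boot=500, seed=2)
    assert ant.verdict == "antagonistic"


def test_classify_input_validation(rng):
    ctrl = rng.normal(10, 1, 5)
    singles = {"A": rng.normal(10, 1, 5)}
    with pytest.raises(NullModelError):
        classify_interaction([1.0], ctrl, singles, "additive")
    with pytest.raises(NullModelError):
        classify_interaction(rng.normal(10, 1, 5), ctrl, singles, "bliss")
    with pytest.raises(NullModelError):
        classify_interaction(rng.normal(10, 1, 5), ctrl, {"A": [1.0]}, "additive")
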