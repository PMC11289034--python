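"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities by brute force (exhaustive
enumeration, direct formula evaluation) without calling the code paths
they check.
"""

from itertools import product

import numpy as np

from pestimix import GenerativeParams, draw_response_values


def exhaustive_additive_prediction_distribution(
    control: np.ndarray, singles: dict[str, np.ndarray]
) -> np.ndarray:
    """Every equally likely with-replacement resample of all groups, and the
    additive prediction of each: sum_i mean_i* - k * mu_c*.

    Feasible only for tiny groups (total enumeration is prod(n_g ** n_g)).
    """
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(v, dtype=float) for v in singles.values()
    ]
    mean_sets = []
    for g in groups:
        means = [np.mean([g[i] for i in idx]) for idx in product(range(g.size), repeat=g.size)]
        mean_sets.append(np.array(means))
    k = len(singles)
    out = []
    for combo in product(*mean_sets):
        mu_c = combo[0]
        out.append(sum(combo[1:]) - k * mu_c)
    return np.array(out)


def quantile_bracket_check(
    exact: np.ndarray, value: float, q: float, slack: float = 0.01
) -> bool:
    """Whether `value` is a valid q-quantile of the discrete distribution
    `exact`, up to `slack` probability mass.

    The exhaustively enumerated resample distribution has atoms, so two
    correct quantile estimators can return different nearby atoms; comparing
    cumulative probabilities at the candidate value is estimator-agnostic.
    """
    below = np.mean(exact < value - 1e-12)
    at_or_below = np.mean(exact <= value + 1e-12)
    return below <= q + slack and at_or_below >= q - slack


def simulate_mixture_experiment(
    params: GenerativeParams,
    response: str,
    codes: list[str],
    rng: np.random.Generator,
    n_control: int = 20,
    n_single: int = 5,
    n_mix: int = 20,
    rate: str = "abrupt",
):
    """One synthetic experiment: control, per-pesticide single arms, and the
    full-composition mixture arm, drawn from the generative model."""
    control = draw_response_values(params, response, (), "none", n_control, rng)
    singles = {
        c: draw_response_values(params, response, (c,), rate, n_single, rng)
        for c in codes
    }
    mixture = draw_response_values(params, response, tuple(codes), rate, n_mix, rng)
    return control, singles, mixture
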