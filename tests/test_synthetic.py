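import dataclasses

import numpy as np
import pytest

from pestimix import (
    GenerativeParams,
    SyntheticError,
    build_response_table,
    draw_response_values,
    expected_response,
    generate_dataset,
    records_from_csv,
    records_to_csv,
)
from pestimix.metrics import RESPONSES
from pestimix.synthetic import ReplicateRecord


def _toy_params(gamma: float = 0.0, lam: float = 1.0) -> GenerativeParams:
    """Minimal hand-checkable parameter set (EC has an unbounded range)."""
    return GenerativeParams(
        control_means={"LD": 0.5, "WSA": 50.0, "MWD": 1.0, "pH": 7.0, "EC": 10.0},
        single_effects={p: {"Imi": 0.1, "Epo": 0.2} for p in RESPONSES},
        interaction_slope={p: gamma for p in RESPONSES},
        gradual_attenuation={p: lam for p in RESPONSES},
        noise_sd={p: 0.0 for p in RESPONSES},
        ph_triplicate_sd=0.0,
    )


def test_expected_response_control_identity(paper_params):
    for p in RESPONSES:
        assert expected_response(paper_params, p, (), "none") == \
            paper_params.control_means[p]


def test_expected_response_hand_values():
    # mu=10, e={0.1, 0.2}: additive-in-effects gives 13.0; gamma=-0.4 on the
    # one-beyond-first pesticide pulls it to 9.0
    assert expected_response(_toy_params(), "EC", ("Imi", "Epo"), "abrupt") == \
        pytest.approx(13.0)
    assert expected_response(_toy_params(gamma=-0.4), "EC", ("Imi", "Epo"), "abrupt") == \
        pytest.approx(9.0)


def test_expected_response_clamped_to_valid_range():
    params = _toy_params()
    params.single_effects["WSA"]["Imi"] = 5.0  # would exceed 100%
    assert expected_response(params, "WSA", ("Imi",), "abrupt") == 100.0
    params.single_effects["LD"]["Imi"] = -5.0
    assert expected_response(params, "LD", ("Imi",), "abrupt") == 0.0


def test_expected_response_errors(paper_params):
    with pytest.raises(SyntheticError):
        expected_response(paper_params, "yield", (), "abrupt")
    with pytest.raises(SyntheticError):
        expected_response(_toy_params(), "EC", ("Zzz",), "abrupt")


def test_gradual_attenuation_shrinks_every_effect_magnitude():
    full = _toy_params(gamma=-0.25)
    damp = _toy_params(gamma=-0.25, lam=0.5)
    for resp in RESPONSES:
        for comp in (("Imi",), ("Epo",), ("Imi", "Epo")):
            mu = full.control_means[resp]
            e_abrupt = expected_response(full, resp, comp, "abrupt") - mu
            e_gradual = expected_response(damp, resp, comp, "gradual") - mu
            assert abs(e_gradual) < abs(e_abrupt)
            assert e_gradual == pytest.approx(0.5 * e_abrupt)


def test_expected_ld_nonincreasing_in_richness(paper_params, panel):
    # negative interaction slope dominates the small positive singles
    chain = [tuple(panel.codes[:k]) for k in range(11)]
    vals = [expected_response(paper_params, "LD", c, "abrupt") for c in chain]
    assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def test_round_trip_zero_noise(default_design, paper_params):
    params = paper_params.noise_free()
    records = generate_dataset(default_design, params)
    table = build_response_table(records)
    by_arm = {a.arm_id: a for a in default_design}
    for (arm_id, rep), grp in table.groupby(["arm_id", "replicate"]):
        arm = by_arm[arm_id]
        comp = arm.composition_per_replicate[rep]
        for _, row in grp.iterrows():
            want = expected_response(params, row["response"], comp, arm.rate)
            assert row["value"] == pytest.approx(want, abs=1e-9)


def test_generation_deterministic_byte_identical(default_design, paper_params, tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    records_to_csv(generate_dataset(default_design, paper_params), a)
    records_to_csv(generate_dataset(default_design, paper_params), b)
    assert a.read_bytes() == b.read_bytes()
    other = dataclasses.replace(paper_params, seed=paper_params.seed + 1)
    records_to_csv(generate_dataset(default_design, other), b)
    assert a.read_bytes() != b.read_bytes()


def test_paper_like_preset_reproduces_mixture_decline(paper_params, panel, rng):
    # Monte-Carlo means: the full 10-mixture depresses litter decomposition
    # below control while single pesticides stay neutral-to-positive
    ctrl = draw_response_values(paper_params, "LD", (), "none", 400, rng)
    mix = draw_response_values(paper_params, "LD", panel.codes, "abrupt", 400, rng)
    assert mix.mean() < ctrl.mean() - 0.05
    for code in panel.codes:
        single = draw_response_values(paper_params, "LD", (code,), "abrupt", 400, rng)
        assert single.mean() >= ctrl.mean() - 0.01


def test_infeasible_mwd_target_names_replicate(default_design, paper_params):
    params = dataclasses.replace(
        paper_params.noise_free(),
        control_means={**paper_params.control_means, "MWD": 3.5},
    )
    with pytest.raises(SyntheticError, match="replicate 0.*MWD|MWD.*replicate 0"):
        generate_dataset(default_design, params)


def test_raw_csv_round_trip(default_design, paper_params, tmp_path):
    records = generate_dataset(default_design, paper_params)
    path = tmp_path / "raw.csv"
    records_to_csv(records, path)
    loaded = records_from_csv(path)
    assert loaded == records


def test_raw_csv_missing_column_is_named(default_design, paper_params, tmp_path):
    records = generate_dataset(default_design, paper_params)
    path = tmp_path / "raw.csv"
    records_to_csv(records, path)
    lines = path.read_text().splitlines()
    cols = lines[0].split(",")
    drop = cols.index("coarse_matter_g")
    broken = "\n".join(
        ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
        for line in lines
    )
    bad = tmp_path / "bad.csv"
    bad.write_text(broken)
    with pytest.raises(SyntheticError, match="coarse_matter_g"):
        records_from_csv(bad)


def test_raw_csv_row_level_validation(default_design, paper_params, tmp_path):
    records = generate_dataset(default_design, paper_params)
    path = tmp_path / "raw.csv"
    records_to_csv(records, path)
    lines = path.read_text().splitlines()
    cols = lines[0].split(",")
    row = lines[1].split(",")
    row[cols.index("tea_final_mg")] = "400.0"  # exceeds the 300 mg initial
    bad = tmp_path / "bad.csv"
    bad.write_text("\n".join([lines[0], ",".join(row), *lines[2:]]))
    with pytest.raises(SyntheticError, match="line 2"):
        records_from_csv(bad)


def test_record_invariants_rejected():
    ok = dict(
        arm_id="a", replicate=0, composition=(), tea_initial_mg=300.0,
        tea_final_mg=150.0, wsa_total_g=4.0, wet_sieve_stable_g=2.0,
        coarse_matter_g=0.5, dry_fraction_masses_g=(4.0, 4.0, 4.0, 4.0, 4.0),
        ph_triplicate=(7.0, 7.0, 7.0), ec_value=50.0,
    )
    ReplicateRecord(**ok)
    with pytest.raises(SyntheticError):
        ReplicateRecord(**{**ok, "tea_final_mg": 301.0})
    with pytest.raises(SyntheticError):
        ReplicateRecord(**{**ok, "coarse_matter_g": 2.5})
    with pytest.raises(SyntheticError):
        ReplicateRecord(**{**ok, "dry_fraction_masses_g": (0.0,) * 5})


def test_preset_validation():
    with pytest.raises(SyntheticError):
        GenerativeParams.preset("bogus")
    with pytest.raises(SyntheticError):
        dataclasses.replace(GenerativeParams.preset(), gradual_attenuation={})
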