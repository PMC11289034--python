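"""Synthetic replicate-level data with the statistical structure the
analysis assumes.

The generative model is multiplicative in the control baseline with a
linear interaction ramp: for a composition S applied at rate r, the
expected response is

    mu_p * (1 + a_r * (sum_{i in S} e_{p,i} + gamma_p * max(0, |S| - 1)))

with a_abrupt = 1 and a_gradual = lambda_p in (0, 1]. Positive single
effects e and a negative interaction slope gamma reproduce the qualitative
field pattern "single pesticides neutral-to-positive, mixtures negative",
and make the additive/multiplicative/dominative null models right or wrong
by construction (gamma = 0 yields an exactly additive generator on the
mean-difference scale).

Generated targets are inverted into raw measurables (tea-bag masses,
wet-sieve masses, dry-sieve fraction masses, pH triplicates) so that the
metric formulas recover them; with zero noise the round trip is exact.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .design import TreatmentArm
from .metrics import RESPONSES, SieveSpec, compute_mwd

logger = logging.getLogger("pestimix")

#: valid range per response used for post-noise clamping
RESPONSE_RANGES = {
    "LD": (0.0, 1.0),
    "WSA": (0.0, 100.0),
    "MWD": (1e-9, math.inf),
    "pH": (0.0, 14.0),
    "EC": (0.0, math.inf),
}

# Reference dry-sieve mass distributions (proportions, coarsest class first)
# whose convex combinations span the attainable mean-weight-diameter range.
_COARSE_HEAVY = (0.40, 0.30, 0.20, 0.07, 0.03)
_FINE_HEAVY = (0.02, 0.08, 0.30, 0.35, 0.25)

_PANEL_CODES = ("Imi", "Epo", "Bos", "Dif", "Nap", "Cyp", "Sme", "Met", "Pen", "Clo")


class SyntheticError(ValueError):
    """Invalid generative parameters or infeasible target inversion."""


def _effects(values: Mapping[str, float]) -> dict[str, float]:
    return {c: float(values.get(c, 0.0)) for c in _PANEL_CODES}


@dataclass
class GenerativeParams:
    """Parameters of the synthetic microcosm generator.

    Effects are dimensionless proportional changes of the control mean;
    noise SDs are on the response scale (LD fraction, WSA percentage points,
    MWD mm, pH units, EC arbitrary units).
    """

    control_means: dict[str, float]
    single_effects: dict[str, dict[str, float]]
    interaction_slope: dict[str, float]
    gradual_attenuation: dict[str, float]
    noise_sd: dict[str, float]
    ph_triplicate_sd: float = 0.02
    tea_initial_mg: float = 300.0
    soil_mass_g: float = 30.0
    wsa_total_g: float = 4.0
    dry_sieve_mass_g: float = 20.0
    coarse_mean_g: float = 0.6
    coarse_sd_g: float = 0.15
    coarse_bounds_g: tuple[float, float] = (0.2, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in RESPONSES:
            if p not in self.control_means:
                raise SyntheticError(f"missing control mean for {p!r}")
            if p not in self.noise_sd or self.noise_sd[p] < 0:
                raise SyntheticError(f"noise SD for {p!r} missing or negative")
            lam = self.gradual_attenuation.get(p)
            if lam is None or not 0 < lam <= 1:
                raise SyntheticError(f"gradual attenuation for {p!r} must be in (0, 1]")
        if not 0 <= self.control_means["LD"] <= 1:
            raise SyntheticError("control LD must be a mass-loss fraction in [0, 1]")
        if not 0 <= self.control_means["WSA"] <= 100:
            raise SyntheticError("control WSA must be a percentage in [0, 100]")
        if self.control_means["MWD"] <= 0:
            raise SyntheticError("control MWD must be positive")
        if self.ph_triplicate_sd < 0:
            raise SyntheticError("pH triplicate SD must be >= 0")

    def noise_free(self) -> "GenerativeParams":
        """Copy with every noise source set to zero (for round-trip checks)."""
        return replace(
            self,
            noise_sd={p: 0.0 for p in RESPONSES},
            ph_triplicate_sd=0.0,
        )

    def to_dict(self) -> dict:
        return {
            "control_means": dict(self.control_means),
            "single_effects": {p: dict(v) for p, v in self.single_effects.items()},
            "interaction_slope": dict(self.interaction_slope),
            "gradual_attenuation": dict(self.gradual_attenuation),
            "noise_sd": dict(self.noise_sd),
            "ph_triplicate_sd": self.ph_triplicate_sd,
            "tea_initial_mg": self.tea_initial_mg,
            "soil_mass_g": self.soil_mass_g,
            "wsa_total_g": self.wsa_total_g,
            "dry_sieve_mass_g": self.dry_sieve_mass_g,
            "coarse_mean_g": self.coarse_mean_g,
            "coarse_sd_g": self.coarse_sd_g,
            "coarse_bounds_g": list(self.coarse_bounds_g),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeParams":
        d = dict(d)
        d["coarse_bounds_g"] = tuple(d.get("coarse_bounds_g", (0.2, 1.2)))
        return cls(**d)

    @classmethod
    def preset(cls, name: str = "paper_like", seed: int = 0) -> "GenerativeParams":
        """Named parameter presets.

        ``paper_like``: six pesticides stimulate decomposition, imidacloprid
        stimulates WSA, napropamide and metrafenone stimulate MWD; a negative
        interaction slope turns joint effects negative (strongly so for
        litter decomposition); gradual application attenuates effects.

        ``null``: same single effects but zero interaction slope and no
        gradual attenuation — an exactly additive generator used for
        null-model calibration.
        """
        base = dict(
            control_means={"LD": 0.55, "WSA": 55.0, "MWD": 1.00, "pH": 6.8, "EC": 60.0},
            single_effects={
                # positive LD responders mirror the observed single-pesticide pattern
                "LD": _effects({c: 0.06 for c in ("Dif", "Nap", "Cyp", "Sme", "Met", "Clo")}),
                "WSA": _effects({"Imi": 0.06}),
                "MWD": _effects({"Nap": 0.06, "Met": 0.06}),
                "pH": _effects({}),
                "EC": _effects({}),
            },
            noise_sd={"LD": 0.03, "WSA": 3.0, "MWD": 0.05, "pH": 0.05, "EC": 3.0},
            seed=seed,
        )
        if name == "paper_like":
            return cls(
                interaction_slope={"LD": -0.07, "WSA": -0.05, "MWD": -0.02,
                                   "pH": 0.004, "EC": -0.01},
                gradual_attenuation={p: 0.6 for p in RESPONSES},
                **base,
            )
        if name == "null":
            return cls(
                interaction_slope={p: 0.0 for p in RESPONSES},
                gradual_attenuation={p: 1.0 for p in RESPONSES},
                **base,
            )
        raise SyntheticError(f"unknown preset {name!r} (use 'paper_like' or 'null')")


def expected_response(
    params: GenerativeParams,
    response: str,
    composition: Iterable[str],
    rate: str,
) -> float:
    """Noise-free expected value of one response for one treated unit."""
    if response not in RESPONSES:
        raise SyntheticError(f"unknown response {response!r}")
    comp = tuple(composition)
    mu = params.control_means[response]
    if not comp:
        return mu
    eff = params.single_effects.get(response, {})
    missing = [c for c in comp if c not in eff]
    if missing:
        raise SyntheticError(f"no single effect defined for {missing} on {response}")
    a = params.gradual_attenuation[response] if rate == "gradual" else 1.0
    total = sum(eff[c] for c in comp)
    total += params.interaction_slope.get(response, 0.0) * max(0, len(comp) - 1)
    lo, hi = RESPONSE_RANGES[response]
    return float(min(max(mu * (1.0 + a * total), lo), hi))


def draw_response_values(
    params: GenerativeParams,
    response: str,
    composition: Iterable[str],
    rate: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n independent noisy draws of one response, clamped to its valid range."""
    mean = expected_response(params, response, composition, rate)
    vals = mean + rng.normal(0.0, params.noise_sd[response], size=n)
    lo, hi = RESPONSE_RANGES[response]
    n_clamped = int(np.sum((vals < lo) | (vals > hi)))
    if n_clamped:
        logger.info("clamped %d/%d %s draws to [%s, %s]", n_clamped, n, response, lo, hi)
    return np.clip(vals, lo, hi)


@dataclass
class ReplicateRecord:
    """Raw measurables of one microcosm, as harvested."""

    arm_id: str
    replicate: int
    composition: tuple[str, ...]
    tea_initial_mg: float
    tea_final_mg: float
    wsa_total_g: float
    wet_sieve_stable_g: float
    coarse_matter_g: float
    dry_fraction_masses_g: tuple[float, ...]
    ph_triplicate: tuple[float, float, float]
    ec_value: float

    def __post_init__(self) -> None:
        label = f"arm {self.arm_id!r} replicate {self.replicate}"
        if not 0 <= self.tea_final_mg <= self.tea_initial_mg:
            raise SyntheticError(
                f"{label}: tea_final_mg {self.tea_final_mg} outside "
                f"[0, {self.tea_initial_mg}]"
            )
        if not 0 <= self.coarse_matter_g <= self.wet_sieve_stable_g <= self.wsa_total_g:
            raise SyntheticError(
                f"{label}: need 0 <= coarse <= wet_sieve_stable <= total, got "
                f"{self.coarse_matter_g}, {self.wet_sieve_stable_g}, {self.wsa_total_g}"
            )
        if any(m < 0 for m in self.dry_fraction_masses_g) or sum(self.dry_fraction_masses_g) <= 0:
            raise SyntheticError(f"{label}: dry fraction masses must be >= 0, total > 0")
        if len(self.ph_triplicate) != 3:
            raise SyntheticError(f"{label}: pH triplicate must have 3 readings")


def _allocate_dry_fractions(
    target_mwd: float,
    total_g: float,
    spec: SieveSpec,
    label: str,
) -> tuple[float, ...]:
    """Fraction masses whose mean weight diameter equals `target_mwd`.

    Masses are a convex combination of a coarse-heavy and a fine-heavy
    reference distribution; targets outside the attainable band raise
    rather than clamp.
    """
    mwd_hi = compute_mwd([w * total_g for w in _COARSE_HEAVY], spec)
    mwd_lo = compute_mwd([w * total_g for w in _FINE_HEAVY], spec)
    if not mwd_lo <= target_mwd <= mwd_hi:
        raise SyntheticError(
            f"{label}: target MWD {target_mwd:.4f} mm outside attainable "
            f"range [{mwd_lo:.4f}, {mwd_hi:.4f}] mm"
        )
    alpha = (target_mwd - mwd_lo) / (mwd_hi - mwd_lo)
    return tuple(
        total_g * (alpha * wc + (1.0 - alpha) * wf)
        for wc, wf in zip(_COARSE_HEAVY, _FINE_HEAVY)
    )


def generate_dataset(
    design: Sequence[TreatmentArm],
    params: GenerativeParams,
    spec: SieveSpec | None = None,
) -> list[ReplicateRecord]:
    """Simulate raw measurables for every replicate of a design.

    Deterministic given ``params.seed``: responses are drawn per replicate
    as expected value + Gaussian noise, then inverted into tea masses,
    wet-sieve masses, dry-sieve fraction masses, pH triplicates, and EC.
    """
    spec = spec or SieveSpec()
    rng = np.random.default_rng(params.seed)
    lo_c, hi_c = params.coarse_bounds_g
    a = (lo_c - params.coarse_mean_g) / params.coarse_sd_g
    b = (hi_c - params.coarse_mean_g) / params.coarse_sd_g
    records: list[ReplicateRecord] = []
    for arm in design:
        for rep in range(arm.n_replicates):
            comp = arm.composition_per_replicate[rep]
            targets = {
                p: float(draw_response_values(params, p, comp, arm.rate, 1, rng)[0])
                for p in RESPONSES
            }
            label = f"arm {arm.arm_id!r} replicate {rep}"
            coarse = float(
                stats.truncnorm.rvs(
                    a, b, loc=params.coarse_mean_g, scale=params.coarse_sd_g,
                    random_state=rng,
                )
            )
            stable = coarse + targets["WSA"] / 100.0 * (params.wsa_total_g - coarse)
            fractions = _allocate_dry_fractions(
                targets["MWD"], params.dry_sieve_mass_g, spec, label
            )
            triplicate = tuple(
                targets["pH"] + rng.normal(0.0, params.ph_triplicate_sd)
                for _ in range(3)
            )
            records.append(
                ReplicateRecord(
                    arm_id=arm.arm_id,
                    replicate=rep,
                    composition=comp,
                    tea_initial_mg=params.tea_initial_mg,
                    tea_final_mg=params.tea_initial_mg * (1.0 - targets["LD"]),
                    wsa_total_g=params.wsa_total_g,
                    wet_sieve_stable_g=stable,
                    coarse_matter_g=coarse,
                    dry_fraction_masses_g=fractions,
                    ph_triplicate=triplicate,  # type: ignore[arg-type]
                    ec_value=targets["EC"],
                )
            )
    logger.info("generated %d replicate records", len(records))
    return records


# ---------------------------------------------------------------------------
# raw CSV interface
# ---------------------------------------------------------------------------

RAW_CSV_COLUMNS = [
    "arm_id", "replicate", "composition",
    "tea_initial_mg", "tea_final_mg",
    "wsa_total_g", "wet_sieve_stable_g", "coarse_matter_g",
    "frac_gt2", "frac_1_2", "frac_025_1", "frac_01_025", "frac_lt01",
    "ph_1", "ph_2", "ph_3", "ec_value",
]


def records_to_csv(records: Sequence[ReplicateRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RAW_CSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.arm_id, r.replicate, ";".join(r.composition),
                    repr(r.tea_initial_mg), repr(r.tea_final_mg),
                    repr(r.wsa_total_g), repr(r.wet_sieve_stable_g),
                    repr(r.coarse_matter_g),
                    *[repr(m) for m in r.dry_fraction_masses_g],
                    *[repr(v) for v in r.ph_triplicate],
                    repr(r.ec_value),
                ]
            )


def records_from_csv(path: str | Path) -> list[ReplicateRecord]:
    """Load and validate a raw replicate CSV (the generator's own schema).

    Schema violations are reported with the offending column or row.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        rows = list(reader)
        header = set(reader.fieldnames or ())
    missing = set(RAW_CSV_COLUMNS) - header
    if missing:
        raise SyntheticError(f"raw CSV missing columns: {sorted(missing)}")
    records = []
    for i, r in enumerate(rows, start=2):
        try:
            records.append(
                ReplicateRecord(
                    arm_id=r["arm_id"],
                    replicate=int(r["replicate"]),
                    composition=tuple(c for c in r["composition"].split(";") if c),
                    tea_initial_mg=float(r["tea_initial_mg"]),
                    tea_final_mg=float(r["tea_final_mg"]),
                    wsa_total_g=float(r["wsa_total_g"]),
                    wet_sieve_stable_g=float(r["wet_sieve_stable_g"]),
                    coarse_matter_g=float(r["coarse_matter_g"]),
                    dry_fraction_masses_g=tuple(
                        float(r[c]) for c in
                        ("frac_gt2", "frac_1_2", "frac_025_1", "frac_01_025", "frac_lt01")
                    ),
                    ph_triplicate=(float(r["ph_1"]), float(r["ph_2"]), float(r["ph_3"])),
                    ec_value=float(r["ec_value"]),
                )
            )
        except (SyntheticError, ValueError) as err:
            raise SyntheticError(f"raw CSV line {i}: {err}") from err
    return records
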