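"""Soil-process response variables from raw microcosm measurables.

Litter decomposition from tea-bag mass loss, percent water-stable
aggregates (WSA) from wet sieving with a coarse-matter correction, mean
weight diameter (MWD) from a dry-sieve aggregate size distribution, pH from
triplicate readings, and electrical conductivity as a passthrough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import ReplicateRecord

RESPONSES = ("LD", "WSA", "MWD", "pH", "EC")

#: units of each response as emitted in tidy tables
UNITS = {
    "LD": "fraction",
    "WSA": "percent",
    "MWD": "mm",
    "pH": "pH",
    "EC": "a.u.",
}


class MetricError(ValueError):
    """Raw measurables violate a metric's preconditions."""


@dataclass(frozen=True)
class SieveSpec:
    """Dry-sieve stack for the aggregate size distribution.

    Five size classes result from four sieves under a pre-sieve upper bound:
    (top_bound..a1], (a1..a2], ..., (a4..0]. Class mean diameters are the
    arithmetic midpoints of the class bounds, giving the weights' abscissae
    of the mean-weight-diameter sum.
    """

    apertures_mm: tuple[float, ...] = (2.0, 1.0, 0.25, 0.1)
    top_bound_mm: float = 4.0

    def __post_init__(self) -> None:
        aps = self.apertures_mm
        if not aps or any(a <= 0 for a in aps):
            raise MetricError("sieve apertures must be positive")
        if any(a >= b for a, b in zip(aps[1:], aps[:-1])):
            raise MetricError("sieve apertures must be strictly decreasing")
        if self.top_bound_mm <= aps[0]:
            raise MetricError("top bound must exceed the largest aperture")

    @property
    def n_classes(self) -> int:
        return len(self.apertures_mm) + 1

    @property
    def class_means_mm(self) -> tuple[float, ...]:
        """Mean diameter per size class, coarsest first (default:
        3.0, 1.5, 0.625, 0.175, 0.05 mm)."""
        bounds = (self.top_bound_mm, *self.apertures_mm, 0.0)
        return tuple((hi + lo) / 2.0 for hi, lo in zip(bounds[:-1], bounds[1:]))


def compute_decomposition(initial_mg: float, final_mg: float) -> float:
    """Litter mass-loss fraction 1 - final/initial of a tea bag.

    The complementary remaining fraction is available via
    :func:`remaining_fraction`.
    """
    if not initial_mg > 0:
        raise MetricError(f"initial mass must be positive, got {initial_mg}")
    if not 0 <= final_mg <= initial_mg:
        raise MetricError(
            f"final mass {final_mg} mg outside [0, initial={initial_mg}] mg"
        )
    return 1.0 - final_mg / initial_mg


def remaining_fraction(initial_mg: float, final_mg: float) -> float:
    """Remaining mass fraction final/initial of a tea bag."""
    return 1.0 - compute_decomposition(initial_mg, final_mg)


def compute_wsa(stable_g: float, coarse_g: float, total_g: float = 4.0) -> float:
    """Percent water-stable aggregates, corrected for coarse matter.

    100 * (stable - coarse) / (total - coarse), where `stable_g` is the mass
    retained after wet sieving (aggregates plus coarse matter), `coarse_g`
    the organic debris and sand > 0.25 mm within it, and `total_g` the
    rewetted sample mass (default 4.0 g).
    """
    if coarse_g < 0:
        raise MetricError(f"coarse matter mass must be >= 0, got {coarse_g}")
    if coarse_g >= total_g:
        raise MetricError(
            f"coarse matter {coarse_g} g must be below total {total_g} g"
        )
    if stable_g < coarse_g:
        raise MetricError(
            f"retained mass {stable_g} g below coarse matter {coarse_g} g"
        )
    if stable_g > total_g:
        raise MetricError(
            f"retained mass {stable_g} g exceeds total {total_g} g"
        )
    # ratio first: keeps the result in [0, 100] to the last ulp
    return 100.0 * ((stable_g - coarse_g) / (total_g - coarse_g))


def compute_mwd(
    fraction_masses_g: Sequence[float], spec: SieveSpec | None = None
) -> float:
    """Mean weight diameter (mm): sum over classes of x̄_i * w_i.

    x̄_i is the class mean diameter and w_i the proportion of total mass in
    class i; masses are given coarsest class first, matching
    ``spec.class_means_mm``.
    """
    spec = spec or SieveSpec()
    if len(fraction_masses_g) != spec.n_classes:
        raise MetricError(
            f"expected {spec.n_classes} fraction masses, got {len(fraction_masses_g)}"
        )
    if any(m < 0 for m in fraction_masses_g):
        raise MetricError("fraction masses must be >= 0")
    total = float(sum(fraction_masses_g))
    if total <= 0:
        raise MetricError("total sieved mass must be positive")
    return sum(x * m / total for x, m in zip(spec.class_means_mm, fraction_masses_g))


def average_ph(triplicate: Sequence[float]) -> float:
    """Arithmetic mean of exactly three pH readings of one suspension."""
    vals = list(triplicate)
    if len(vals) != 3:
        raise MetricError(f"pH requires exactly 3 readings, got {len(vals)}")
    if any(v != v or v in (float("inf"), float("-inf")) for v in vals):
        raise MetricError("pH readings must be finite")
    return sum(vals) / 3.0


def build_response_table(
    records: "Sequence[ReplicateRecord]", spec: SieveSpec | None = None
) -> pd.DataFrame:
    """Tidy response table from raw replicate records.

    One row per replicate x response (LD, WSA, MWD, pH, EC), columns
    arm_id, replicate, response, value, units. Metric errors are re-raised
    with the offending replicate named.
    """
    spec = spec or SieveSpec()
    rows = []
    for rec in records:
        try:
            values = {
                "LD": compute_decomposition(rec.tea_initial_mg, rec.tea_final_mg),
                "WSA": compute_wsa(
                    rec.wet_sieve_stable_g, rec.coarse_matter_g, rec.wsa_total_g
                ),
                "MWD": compute_mwd(rec.dry_fraction_masses_g, spec),
                "pH": average_ph(rec.ph_triplicate),
                "EC": rec.ec_value,
            }
        except MetricError as err:
            raise MetricError(
                f"arm {rec.arm_id!r} replicate {rec.replicate}: {err}"
            ) from err
        for resp in RESPONSES:
            rows.append(
                {
                    "arm_id": rec.arm_id,
                    "replicate": rec.replicate,
                    "response": resp,
                    "value": values[resp],
                    "units": UNITS[resp],
                }
            )
    return pd.DataFrame(rows, columns=["arm_id", "replicate", "response", "value", "units"])
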