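"""Factorial pesticide-mixture experiment design.

Encodes the ten-pesticide panel (environmentally realistic peak soil
concentrations from an EU-wide survey of 280 agricultural soils), the
treatment arms of a richness x application-rate factorial (0/1/5/10
pesticides, abrupt vs gradual delivery), and the equal-cumulative-dose
application schedules: the abrupt arm receives each pesticide's full peak
concentration in a single pulse on day 20, the gradual arm receives one
fifth of it every 10 days over the 50-day incubation, so both arms share
the same area under the exposure curve.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("pestimix")

PESTICIDE_TYPES = ("insecticide", "fungicide", "herbicide")
RATES = ("abrupt", "gradual", "none")
SOLVENT_KINDS = ("none", "acetone", "tween", "water", "combined")
RICHNESS_LEVELS = (0, 1, 5, 10)

#: day of the single abrupt pulse within the 50-day incubation
ABRUPT_DAY = 20
#: days of the five equal gradual applications
GRADUAL_DAYS = (10, 20, 30, 40, 50)
#: days on which abrupt / control units receive matched solvent-water handling
HANDLING_DAYS = (10, 20, 30, 40, 50)
#: liquid volume per application event, mL (bookkeeping only)
APPLICATION_VOLUME_ML = 1.0


class DesignError(ValueError):
    """Invalid panel, arm, or design configuration."""


@dataclass(frozen=True)
class Pesticide:
    """One active ingredient of the panel.

    peak_conc is the maximal soil concentration observed across the survey
    sites, in ng active ingredient per g dry soil; it is the cumulative dose
    each treated microcosm receives.
    """

    code: str
    name: str
    ptype: str
    peak_conc: float
    detection_pct: float
    eu_approved: bool

    def __post_init__(self) -> None:
        if len(self.code) != 3:
            raise DesignError(f"pesticide code must be 3 letters, got {self.code!r}")
        if self.ptype not in PESTICIDE_TYPES:
            raise DesignError(f"unknown pesticide type {self.ptype!r}")
        if not self.peak_conc > 0:
            raise DesignError(f"{self.code}: peak_conc must be > 0")
        if not 0 <= self.detection_pct <= 100:
            raise DesignError(f"{self.code}: detection_pct must be in [0, 100]")


class PesticidePanel:
    """Ordered, code-unique collection of pesticides."""

    def __init__(self, pesticides: Iterable[Pesticide]):
        self._pesticides = tuple(pesticides)
        codes = [p.code for p in self._pesticides]
        if len(set(codes)) != len(codes):
            raise DesignError("duplicate pesticide codes in panel")
        self._by_code = {p.code: p for p in self._pesticides}

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(p.code for p in self._pesticides)

    def __len__(self) -> int:
        return len(self._pesticides)

    def __iter__(self) -> Iterator[Pesticide]:
        return iter(self._pesticides)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Pesticide:
        try:
            return self._by_code[code]
        except KeyError:
            raise DesignError(f"unknown pesticide code {code!r}") from None

    def order_index(self, code: str) -> int:
        """Position of a code in panel (catalogue) order; used for tie-breaks."""
        self[code]
        return self.codes.index(code)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PesticidePanel) and self._pesticides == other._pesticides

    def __repr__(self) -> str:
        return f"PesticidePanel({', '.join(self.codes)})"


# Default panel: two insecticides, four fungicides, four herbicides, ordered by
# decreasing occurrence; concentrations are the maxima measured across 280
# conventionally managed fields (ng a.i. per g soil). Asterisked substances in
# the source catalogue (Imi, Epo, Clo) lack current EU approval.
_DEFAULT_PANEL_ROWS = (
    ("Imi", "Imidacloprid", "insecticide", 150.0, 78.0, False),
    ("Epo", "Epoxiconazole", "fungicide", 300.0, 73.0, False),
    ("Bos", "Boscalid", "fungicide", 1200.0, 64.0, True),
    ("Dif", "Diflufenican", "herbicide", 1300.0, 58.0, True),
    ("Nap", "Napropamide", "herbicide", 100.0, 57.0, True),
    ("Cyp", "Cyproconazole", "fungicide", 250.0, 40.0, True),
    ("Sme", "S-metolachlor", "herbicide", 80.0, 39.0, True),
    ("Met", "Metrafenone", "fungicide", 200.0, 22.0, True),
    ("Pen", "Pendimethalin", "herbicide", 1000.0, 20.0, True),
    ("Clo", "Clothianidin", "insecticide", 60.0, 20.0, False),
)


def build_default_panel() -> PesticidePanel:
    """The default 10-pesticide catalogue in survey order."""
    return PesticidePanel(Pesticide(*row) for row in _DEFAULT_PANEL_ROWS)


@dataclass
class TreatmentArm:
    """One treatment arm: rate x richness, with per-replicate compositions.

    Richness-5 arms draw an independent random 5-subset of the panel per
    replicate; richness-1 arms repeat one code; richness-10 arms use the full
    panel; richness-0 arms are controls (optionally solvent checks).
    """

    arm_id: str
    rate: str
    richness: int
    composition_per_replicate: dict[int, tuple[str, ...]]
    n_replicates: int
    solvent_control_kind: str = "none"

    def __post_init__(self) -> None:
        if self.rate not in RATES:
            raise DesignError(f"{self.arm_id}: unknown rate {self.rate!r}")
        if self.solvent_control_kind not in SOLVENT_KINDS:
            raise DesignError(
                f"{self.arm_id}: unknown solvent kind {self.solvent_control_kind!r}"
            )
        if self.n_replicates <= 0:
            raise DesignError(f"{self.arm_id}: n_replicates must be positive")
        if set(self.composition_per_replicate) != set(range(self.n_replicates)):
            raise DesignError(f"{self.arm_id}: replicate indices must be 0..n-1")
        for rep, comp in self.composition_per_replicate.items():
            if len(comp) != self.richness or len(set(comp)) != len(comp):
                raise DesignError(
                    f"{self.arm_id} replicate {rep}: composition must be "
                    f"{self.richness} distinct codes, got {comp}"
                )

    def validate_against_panel(self, panel: PesticidePanel) -> None:
        for rep, comp in self.composition_per_replicate.items():
            for code in comp:
                if code not in panel:
                    raise DesignError(
                        f"{self.arm_id} replicate {rep}: code {code!r} not in panel"
                    )

    @property
    def compositions(self) -> list[tuple[str, ...]]:
        """Compositions in replicate order."""
        return [self.composition_per_replicate[i] for i in range(self.n_replicates)]


@dataclass(frozen=True)
class ApplicationEvent:
    """A single timed liquid application to one arm's microcosms."""

    day: int
    added_conc: Mapping[str, float]
    volume_ml: float = APPLICATION_VOLUME_ML

    def __post_init__(self) -> None:
        if not 0 <= self.day <= 50:
            raise DesignError(f"application day {self.day} outside [0, 50]")
        if any(v < 0 for v in self.added_conc.values()):
            raise DesignError("negative concentration increment")


@dataclass(frozen=True)
class DosingSchedule:
    arm_id: str
    events: tuple[ApplicationEvent, ...]

    def cumulative_dose(self) -> dict[str, float]:
        """Total added concentration per pesticide over all events (ng/g)."""
        total: dict[str, float] = {}
        for ev in self.events:
            for code, inc in ev.added_conc.items():
                total[code] = total.get(code, 0.0) + inc
        return total


@dataclass
class DesignConfig:
    """Parameters of the default factorial layout.

    The single-pesticide replication in the source design is ambiguous
    (10 units per rate vs 10 per pesticide); `replicates_per_single` controls
    replication per pesticide per rate, and `paper_layout=True` selects one
    unit per pesticide per rate (10 units per rate in total).
    """

    richness_levels: tuple[int, ...] = (0, 1, 5, 10)
    rates: tuple[str, ...] = ("abrupt", "gradual")
    replicates_per_single: int = 5
    paper_layout: bool = False
    replicates_five: int = 20
    replicates_ten: int = 20
    control_replicates: int = 20
    solvent_replicates: int = 5
    include_solvent_controls: bool = True

    def __post_init__(self) -> None:
        if not set(self.richness_levels) <= set(RICHNESS_LEVELS):
            raise DesignError(
                f"richness levels must be within {RICHNESS_LEVELS}, "
                f"got {self.richness_levels}"
            )
        for n in (
            self.replicates_per_single,
            self.replicates_five,
            self.replicates_ten,
            self.control_replicates,
            self.solvent_replicates,
        ):
            if n <= 0:
                raise DesignError("replicate counts must be positive")


def build_design(
    panel: PesticidePanel,
    config: DesignConfig | None = None,
    seed: int = 0,
) -> list[TreatmentArm]:
    """Build the full list of treatment arms, deterministic given `seed`.

    The random component is the drawing of 5-subsets for richness-5 arms:
    each replicate receives an independent uniform 5-subset of the panel,
    in panel order.
    """
    config = config or DesignConfig()
    if any(r > len(panel) for r in config.richness_levels):
        raise DesignError("requested richness exceeds panel size")
    rng = np.random.default_rng(seed)
    codes = panel.codes
    arms: list[TreatmentArm] = []

    if 0 in config.richness_levels:
        arms.append(
            TreatmentArm(
                arm_id="control",
                rate="none",
                richness=0,
                composition_per_replicate={i: () for i in range(config.control_replicates)},
                n_replicates=config.control_replicates,
                solvent_control_kind="acetone",
            )
        )
        if config.include_solvent_controls:
            for kind in ("acetone", "tween", "water", "combined"):
                arms.append(
                    TreatmentArm(
                        arm_id=f"solvent_{kind}",
                        rate="none",
                        richness=0,
                        composition_per_replicate={
                            i: () for i in range(config.solvent_replicates)
                        },
                        n_replicates=config.solvent_replicates,
                        solvent_control_kind=kind,
                    )
                )

    n_single = 1 if config.paper_layout else config.replicates_per_single
    for rate in config.rates:
        if 1 in config.richness_levels:
            for code in codes:
                arms.append(
                    TreatmentArm(
                        arm_id=f"{rate}_one_{code}",
                        rate=rate,
                        richness=1,
                        composition_per_replicate={
                            i: (code,) for i in range(n_single)
                        },
                        n_replicates=n_single,
                    )
                )
        if 5 in config.richness_levels:
            comps = {}
            for i in range(config.replicates_five):
                drawn = set(rng.choice(codes, size=5, replace=False))
                comps[i] = tuple(c for c in codes if c in drawn)  # panel order
            arms.append(
                TreatmentArm(
                    arm_id=f"{rate}_five",
                    rate=rate,
                    richness=5,
                    composition_per_replicate=comps,
                    n_replicates=config.replicates_five,
                )
            )
        if 10 in config.richness_levels:
            arms.append(
                TreatmentArm(
                    arm_id=f"{rate}_ten",
                    rate=rate,
                    richness=10,
                    composition_per_replicate={
                        i: codes for i in range(config.replicates_ten)
                    },
                    n_replicates=config.replicates_ten,
                )
            )
    for arm in arms:
        arm.validate_against_panel(panel)
    logger.info("built design: %d arms, %d microcosms",
                len(arms), sum(a.n_replicates for a in arms))
    return arms


def build_dosing_schedule(arm: TreatmentArm, panel: PesticidePanel) -> DosingSchedule:
    """Equal-cumulative-dose schedule for one arm.

    Uses the union of codes over replicates (richness-1/10 arms are
    homogeneous; for richness-5 arms the schedule describes per-unit handling
    and each unit receives only its own composition — the increments here are
    the per-pesticide doses a unit receives *if* its composition contains that
    pesticide).
    """
    arm.validate_against_panel(panel)
    treated = [c for c in panel.codes
               if any(c in comp for comp in arm.composition_per_replicate.values())]
    events: list[ApplicationEvent] = []
    if arm.rate == "abrupt":
        for day in HANDLING_DAYS:
            if day == ABRUPT_DAY:
                events.append(ApplicationEvent(
                    day=day,
                    added_conc={c: panel[c].peak_conc for c in treated},
                ))
            else:  # matched water-only handling
                events.append(ApplicationEvent(day=day, added_conc={}))
    elif arm.rate == "gradual":
        for day in GRADUAL_DAYS:
            events.append(ApplicationEvent(
                day=day,
                added_conc={c: panel[c].peak_conc / 5.0 for c in treated},
            ))
    else:  # controls: solvent-water handling on every handling day
        for day in HANDLING_DAYS:
            events.append(ApplicationEvent(day=day, added_conc={}))
    return DosingSchedule(arm_id=arm.arm_id, events=tuple(events))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

PANEL_CSV_COLUMNS = ["code", "name", "ptype", "peak_conc_ng_per_g",
                     "detection_pct", "eu_approved"]
DESIGN_CSV_COLUMNS = ["arm_id", "rate", "richness", "replicate", "composition"]


def panel_to_csv(panel: PesticidePanel, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PANEL_CSV_COLUMNS)
        for p in panel:
            w.writerow([p.code, p.name, p.ptype, p.peak_conc,
                        p.detection_pct, str(p.eu_approved).lower()])


def panel_from_csv(path: str | Path) -> PesticidePanel:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    missing = set(PANEL_CSV_COLUMNS) - (set(rows[0]) if rows else set())
    if missing:
        raise DesignError(f"panel CSV missing columns: {sorted(missing)}")
    return PesticidePanel(
        Pesticide(
            code=r["code"],
            name=r["name"],
            ptype=r["ptype"],
            peak_conc=float(r["peak_conc_ng_per_g"]),
            detection_pct=float(r["detection_pct"]),
            eu_approved=r["eu_approved"].strip().lower() in ("true", "1", "yes"),
        )
        for r in rows
    )


def design_to_csv(arms: Sequence[TreatmentArm], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DESIGN_CSV_COLUMNS)
        for arm in arms:
            for rep in range(arm.n_replicates):
                w.writerow([arm.arm_id, arm.rate, arm.richness, rep,
                            ";".join(arm.composition_per_replicate[rep])])


def design_from_csv(path: str | Path) -> list[TreatmentArm]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    missing = set(DESIGN_CSV_COLUMNS) - (set(rows[0]) if rows else set())
    if missing:
        raise DesignError(f"design CSV missing columns: {sorted(missing)}")
    by_arm: dict[str, list[dict]] = {}
    order: list[str] = []
    for r in rows:
        if r["arm_id"] not in by_arm:
            order.append(r["arm_id"])
        by_arm.setdefault(r["arm_id"], []).append(r)
    arms = []
    for arm_id in order:
        arm_rows = by_arm[arm_id]
        comps = {
            int(r["replicate"]): tuple(c for c in r["composition"].split(";") if c)
            for r in arm_rows
        }
        arms.append(
            TreatmentArm(
                arm_id=arm_id,
                rate=arm_rows[0]["rate"],
                richness=int(arm_rows[0]["richness"]),
                composition_per_replicate=comps,
                n_replicates=len(arm_rows),
            )
        )
    return arms
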