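"""End-to-end orchestration: design -> simulate (or load) -> metrics ->
effect sizes -> null models -> report.

Every stage is a plain function over the library types; `run_pipeline`
chains them, writes the CSV artifacts with provenance headers (config
hash, seed, package version), and emits a text summary of per-response
interaction verdicts. A single global seed spawns independent per-stage
seeds, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    DesignConfig,
    PesticidePanel,
    TreatmentArm,
    build_default_panel,
    build_design,
    build_dosing_schedule,
    design_to_csv,
    panel_to_csv,
)
from .effects import EffectEstimate, bootstrap_mean_difference, paired_rate_contrast, richness_trend
from .metrics import RESPONSES, SieveSpec, build_response_table
from .nullmodels import MODELS, classify_interaction
from .synthetic import (
    GenerativeParams,
    ReplicateRecord,
    generate_dataset,
    records_from_csv,
    records_to_csv,
)

logger = logging.getLogger("pestimix")

_STAGES = ("design", "simulate", "effects", "nullmodels")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    preset: str = "paper_like"
    seed: int = 0
    out_dir: str = "results"
    n_boot_effects: int = 5000
    n_boot_null: int = 1000
    ci_method: str = "bca"
    design: DesignConfig = field(default_factory=DesignConfig)
    params: GenerativeParams | None = None
    raw_csv: str | None = None
    figures: bool = False

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "n_boot_effects": self.n_boot_effects,
            "n_boot_null": self.n_boot_null,
            "ci_method": self.ci_method,
            "design": vars(self.design).copy(),
            "params": self.params.to_dict() if self.params is not None else None,
            "raw_csv": self.raw_csv,
            "figures": self.figures,
        }
        d["design"]["richness_levels"] = list(self.design.richness_levels)
        d["design"]["rates"] = list(self.design.rates)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "design" in d and d["design"] is not None:
            dd = dict(d["design"])
            dd["richness_levels"] = tuple(dd.get("richness_levels", (0, 1, 5, 10)))
            dd["rates"] = tuple(dd.get("rates", ("abrupt", "gradual")))
            d["design"] = DesignConfig(**dd)
        else:
            d["design"] = DesignConfig()
        if d.get("params") is not None:
            d["params"] = GenerativeParams.from_dict(d["params"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("figures")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds spawned from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


def _write_csv(df: pd.DataFrame, path: Path, meta: Mapping[str, object]) -> None:
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping provenance header lines."""
    return pd.read_csv(path, comment="#")


def load_external_raw(path: str | Path) -> list[ReplicateRecord]:
    """Load a compatible raw replicate CSV (validated row by row)."""
    return records_from_csv(path)


# ---------------------------------------------------------------------------
# analysis stages on a tidy response table
# ---------------------------------------------------------------------------

def _arm_index(design: Sequence[TreatmentArm]) -> dict[str, TreatmentArm]:
    return {a.arm_id: a for a in design}


def _values(resp_df: pd.DataFrame, response: str, arm_ids: Sequence[str]) -> np.ndarray:
    sub = resp_df[(resp_df["response"] == response) & (resp_df["arm_id"].isin(arm_ids))]
    return sub["value"].to_numpy()


def compute_effects_table(
    resp_df: pd.DataFrame,
    design: Sequence[TreatmentArm],
    n_boot: int = 5000,
    ci_method: str = "bca",
    seed: int | None = None,
) -> pd.DataFrame:
    """Effect sizes vs control for the pooled One/Five/Ten categories,
    per-rate variants, and gradual-vs-abrupt rate contrasts.

    The pooled "one" category aggregates all single-pesticide replicates
    across pesticides (and, in the rate-pooled rows, across rates).
    """
    arms = _arm_index(design)
    singles = {r: [a.arm_id for a in design if a.richness == 1 and a.rate == r]
               for r in ("abrupt", "gradual")}
    groups: dict[str, list[str]] = {}
    for label, richness in (("one", 1), ("five", 5), ("ten", 10)):
        per_rate = {
            r: [a.arm_id for a in design if a.richness == richness and a.rate == r]
            for r in ("abrupt", "gradual")
        }
        if per_rate["abrupt"] or per_rate["gradual"]:
            groups[label] = per_rate["abrupt"] + per_rate["gradual"]
            for r in ("abrupt", "gradual"):
                if per_rate[r]:
                    groups[f"{r}_{label}"] = per_rate[r]
    if "control" not in arms:
        raise PipelineError("effects stage: design has no 'control' arm")
    ss = np.random.SeedSequence(seed)
    rows = []
    for response in RESPONSES:
        ctrl = _values(resp_df, response, ["control"])
        for label, arm_ids in groups.items():
            est = bootstrap_mean_difference(
                _values(resp_df, response, arm_ids), ctrl,
                n_boot=n_boot, ci_method=ci_method,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
                response=response, arm=label, reference="control",
            )
            rows.append(est)
        for label, richness in (("one", 1), ("five", 5), ("ten", 10)):
            g_ids = [a.arm_id for a in design if a.richness == richness and a.rate == "gradual"]
            a_ids = [a.arm_id for a in design if a.richness == richness and a.rate == "abrupt"]
            if g_ids and a_ids:
                rows.append(paired_rate_contrast(
                    _values(resp_df, response, g_ids),
                    _values(resp_df, response, a_ids),
                    n_boot=n_boot, ci_method=ci_method,
                    seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
                    response=response, arm=f"gradual_vs_abrupt_{label}",
                ))
    return pd.DataFrame(
        [
            {
                "response": e.response, "arm": e.arm, "reference": e.reference,
                "estimate": e.estimate, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "n_boot": e.n_boot, "ci_method": e.ci_method, "seed": e.seed,
            }
            for e in rows
        ]
    )


def compute_trends_table(
    resp_df: pd.DataFrame,
    design: Sequence[TreatmentArm],
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """OLS richness trend per response over all pesticide-bearing and control arms."""
    richness_of = {a.arm_id: a.richness for a in design
                   if a.richness > 0 or a.arm_id == "control"}
    ss = np.random.SeedSequence(seed)
    rows = []
    for response in RESPONSES:
        sub = resp_df[(resp_df["response"] == response)
                      & (resp_df["arm_id"].isin(richness_of))]
        t = richness_trend(
            sub["arm_id"].map(richness_of).to_numpy(dtype=float),
            sub["value"].to_numpy(),
            n_boot=n_boot,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            response=response,
        )
        rows.append({
            "response": t.response, "slope": t.slope, "intercept": t.intercept,
            "ci_low": t.ci_low, "ci_high": t.ci_high, "n_boot": t.n_boot,
            "seed": t.seed,
        })
    return pd.DataFrame(rows)


def compute_nullmodel_table(
    resp_df: pd.DataFrame,
    design: Sequence[TreatmentArm],
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Interaction calls for the five- and ten-pesticide mixtures.

    Follows the published comparison on the overall dataset: abrupt and
    gradual replicates are pooled for the mixture arms, the single arms,
    and therefore the predictions; five-mixture predictions use the
    realized per-replicate compositions.
    """
    by_code: dict[str, list[str]] = {}
    for a in design:
        if a.richness == 1:
            by_code.setdefault(a.composition_per_replicate[0][0], []).append(a.arm_id)
    ss = np.random.SeedSequence(seed)
    rows = []
    for response in RESPONSES:
        ctrl = _values(resp_df, response, ["control"])
        singles = {code: _values(resp_df, response, ids) for code, ids in by_code.items()}
        for label, richness in (("five", 5), ("ten", 10)):
            mix_arms = [a for a in design if a.richness == richness]
            if not mix_arms:
                continue
            mix_ids = [a.arm_id for a in mix_arms]
            comps = [c for a in mix_arms for c in a.compositions]
            mix_vals = _values(resp_df, response, mix_ids)
            for model in MODELS:
                call = classify_interaction(
                    mix_vals, ctrl, singles, model, compositions=comps,
                    n_boot=n_boot,
                    seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
                    response=response, arm=label,
                )
                rows.append({
                    "response": response, "model": model, "arm": label,
                    "predicted": call.prediction.predicted,
                    "ci_low": call.prediction.ci_low,
                    "ci_high": call.prediction.ci_high,
                    "observed": call.observed.estimate,
                    "obs_ci_low": call.observed.ci_low,
                    "obs_ci_high": call.observed.ci_high,
                    "delta": call.delta,
                    "delta_ci_low": call.delta_ci_low,
                    "delta_ci_high": call.delta_ci_high,
                    "verdict": call.verdict,
                    "n_boot": n_boot, "seed": call.prediction.seed,
                })
    return pd.DataFrame(rows)


def write_report(null_df: pd.DataFrame, trend_df: pd.DataFrame, path: Path,
                 meta: Mapping[str, object]) -> str:
    lines = ["pestimix run summary", "====================", ""]
    lines += [f"{k}: {v}" for k, v in meta.items()]
    lines.append("")
    lines.append("Richness trends (OLS slope per unit richness, 95% bootstrap CI):")
    for _, r in trend_df.iterrows():
        lines.append(
            f"  {r['response']:>4}: slope {r['slope']:+.4f} "
            f"[{r['ci_low']:+.4f}, {r['ci_high']:+.4f}]"
        )
    lines.append("")
    lines.append("Null-model interaction verdicts (observed vs predicted joint effect):")
    for _, r in null_df.iterrows():
        lines.append(
            f"  {r['response']:>4} {r['arm']:>5} {r['model']:>14}: "
            f"observed {r['observed']:+.4f}, predicted {r['predicted']:+.4f}, "
            f"delta {r['delta']:+.4f} [{r['delta_ci_low']:+.4f}, "
            f"{r['delta_ci_high']:+.4f}] -> {r['verdict']}"
        )
    text = "\n".join(lines) + "\n"
    path.write_text(text, encoding="utf-8")
    return text


def make_figures(effects_df: pd.DataFrame, null_df: pd.DataFrame, out: Path) -> list[Path]:
    """Plain effect-size and null-model comparison figures (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    pooled = effects_df[effects_df["arm"].isin(["one", "five", "ten"])]
    fig, axes = plt.subplots(1, len(RESPONSES), figsize=(3 * len(RESPONSES), 3.2))
    for ax, response in zip(np.atleast_1d(axes), RESPONSES):
        sub = pooled[pooled["response"] == response]
        x = np.arange(len(sub))
        ax.errorbar(
            x, sub["estimate"],
            yerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
            fmt="o", capsize=3,
        )
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xticks(x, sub["arm"])
        ax.set_title(response)
    fig.suptitle("Effect size vs control (bootstrap 95% CI)")
    fig.tight_layout()
    p = out / "effects.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, len(RESPONSES), figsize=(3 * len(RESPONSES), 3.2))
    for ax, response in zip(np.atleast_1d(axes), RESPONSES):
        sub = null_df[null_df["response"] == response]
        x = np.arange(len(sub))
        ax.errorbar(
            x, sub["predicted"],
            yerr=[sub["predicted"] - sub["ci_low"], sub["ci_high"] - sub["predicted"]],
            fmt="s", capsize=3, label="predicted",
        )
        ax.scatter(x, sub["observed"], marker="o", color="black", label="observed")
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xticks(x, [f"{a}\n{m[:4]}" for a, m in zip(sub["arm"], sub["model"])],
                      fontsize=6)
        ax.set_title(response)
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.suptitle("Null-model predictions vs observed joint effects")
    fig.tight_layout()
    p = out / "nullmodels.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write artifacts to ``config.out_dir``.

    Returns a mapping of artifact names to paths. Fully reproducible: the
    same config (including seed) yields byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    meta = {
        "package": f"pestimix {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "preset": config.preset,
    }
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)

    try:
        stage("design")
        panel = build_default_panel()
        design = build_design(panel, config.design, seed=seeds["design"])
        panel_to_csv(panel, out / "panel.csv")
        design_to_csv(design, out / "design.csv")
        artifacts["panel"] = out / "panel.csv"
        artifacts["design"] = out / "design.csv"
        # dose bookkeeping check: every schedule conserves the peak dose
        for arm in design:
            build_dosing_schedule(arm, panel)
    except Exception as err:
        raise PipelineError(f"design stage failed: {err}") from err

    try:
        stage("simulate")
        if config.raw_csv is not None:
            records = load_external_raw(config.raw_csv)
        else:
            params = config.params or GenerativeParams.preset(config.preset)
            params = dataclasses.replace(params, seed=seeds["simulate"])
            records = generate_dataset(design, params)
        records_to_csv(records, out / "raw.csv")
        artifacts["raw"] = out / "raw.csv"
    except Exception as err:
        raise PipelineError(f"simulate stage failed: {err}") from err

    try:
        stage("metrics")
        resp_df = build_response_table(records, SieveSpec())
        _write_csv(resp_df, out / "responses.csv", meta | {"stage": "metrics"})
        artifacts["responses"] = out / "responses.csv"
    except Exception as err:
        raise PipelineError(f"metrics stage failed: {err}") from err

    try:
        stage("effects")
        effects_df = compute_effects_table(
            resp_df, design, n_boot=config.n_boot_effects,
            ci_method=config.ci_method, seed=seeds["effects"],
        )
        trends_df = compute_trends_table(
            resp_df, design, n_boot=config.n_boot_null, seed=seeds["effects"],
        )
        _write_csv(effects_df, out / "effects.csv", meta | {"stage": "effects"})
        _write_csv(trends_df, out / "trends.csv", meta | {"stage": "effects"})
        artifacts["effects"] = out / "effects.csv"
        artifacts["trends"] = out / "trends.csv"
    except Exception as err:
        raise PipelineError(f"effects stage failed: {err}") from err

    try:
        stage("nullmodels")
        null_df = compute_nullmodel_table(
            resp_df, design, n_boot=config.n_boot_null, seed=seeds["nullmodels"],
        )
        _write_csv(null_df, out / "nullmodel.csv", meta | {"stage": "nullmodels"})
        artifacts["nullmodel"] = out / "nullmodel.csv"
    except Exception as err:
        raise PipelineError(f"nullmodels stage failed: {err}") from err

    try:
        stage("report")
        write_report(null_df, trends_df, out / "report.txt", meta)
        artifacts["report"] = out / "report.txt"
        if config.figures:
            for p in make_figures(effects_df, null_df, out):
                artifacts[p.stem + "_png"] = p
    except Exception as err:
        raise PipelineError(f"report stage failed: {err}") from err

    config.to_file(out / "config.yaml")
    artifacts["config"] = out / "config.yaml"
    logger.info("run complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
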