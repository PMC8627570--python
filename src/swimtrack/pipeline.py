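"""End-to-end orchestration: simulate -> (render -> track) -> kinematics ->
performance -> stats, with per-stage artifacts and a provenance log.

The two canonical runs are the full synthetic study (cohort generation
through statistics) and the analysis-only run on user-supplied midline CSV
files.  Every tolerance and threshold any stage uses is carried in one flat
``RunConfig`` and echoed into the run directory, so a result can always be
traced back to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SwimtrackError, ValidationError
from .io import read_midlines_csv, write_midlines_csv
from .kinematics import compute_wave_kinematics
from .performance import add_performance_columns
from .stats import (
    check_parametric_assumptions,
    holm_sidak_posthoc,
    mixed_model_speed,
    one_way_anova,
    regress_on_regeneration,
)
from .synthetic import (
    CohortSpec,
    RenderSpec,
    generate_cohort,
    generate_midline_sequence,
    params_from_row,
    render_frames,
)
from .tracking import track_stack

__all__ = ["RunConfig", "run_pipeline", "run_stats", "analyze_trials"]

_FLOAT_FMT = "%.10g"

#: responses compared across treatments in the summary statistics
DEFAULT_RESPONSES = (
    "speed_bl_s", "frequency_hz", "wavelength_bl", "amp_pp_bl",
    "amp_ratio", "strouhal", "stride_length_bl",
)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "swimtrack_run"
    seed: int = 0
    # simulate stage
    simulate: bool = True
    n_sham: int = 3
    n_fifth_gill: int = 11
    n_mid_body: int = 3
    trials_per_individual: int = 3
    frame_rate_hz: float = 250.0
    trial_duration_s: float = 1.2
    noise_sd_bl: float = 0.0
    render: bool = False
    pixels_per_bl: float = 100.0
    write_midlines: bool = False
    # analysis-only entry point
    midline_csv: str | None = None
    midline_frame_rate_hz: float | None = None
    # kinematics stage
    n_points: int = 100
    steady_tolerance: float = 0.15
    # performance stage
    amplitude_convention: str = "half_pp"
    # stats stage
    alpha: float = 0.05
    responses: tuple[str, ...] = DEFAULT_RESPONSES

    def validate(self) -> None:
        if not self.simulate:
            if self.midline_csv is None:
                raise ValidationError(
                    "config needs either simulate=True or a midline_csv path"
                )
            if not Path(self.midline_csv).exists():
                raise ValidationError(f"midline_csv not found: {self.midline_csv}")
            if not self.midline_frame_rate_hz:
                raise ValidationError("midline_frame_rate_hz required with midline_csv")
        if self.trial_duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValidationError("durations and frame rates must be positive")
        if self.amplitude_convention not in ("half_pp", "pp"):
            raise ValidationError("amplitude_convention must be 'half_pp' or 'pp'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["responses"] = list(data["responses"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _simulate_trials(cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Generate the cohort and extract kinematics for every trial."""
    spec = CohortSpec(
        n_per_group={
            "sham": cfg.n_sham,
            "fifth_gill": cfg.n_fifth_gill,
            "mid_body": cfg.n_mid_body,
        },
        trials_per_individual=cfg.trials_per_individual,
        seed=cfg.seed,
    )
    cohort = generate_cohort(spec)
    cohort.to_csv(out / "cohort.csv", index=False, float_format=_FLOAT_FMT)

    n_frames = int(round(cfg.frame_rate_hz * cfg.trial_duration_s))
    rows = []
    mid_dir = out / "midlines"
    if cfg.write_midlines:
        mid_dir.mkdir(exist_ok=True)
    for _, row in cohort.iterrows():
        params = params_from_row(row, noise_sd_bl=cfg.noise_sd_bl)
        sm = generate_midline_sequence(
            params, cfg.frame_rate_hz, n_frames, n_points=cfg.n_points
        )
        seq = sm.observed
        if cfg.render:
            rendered = render_frames(seq, RenderSpec(pixels_per_bl=cfg.pixels_per_bl))
            seq = track_stack(rendered.frames, cfg.frame_rate_hz, n_points=cfg.n_points)
        if cfg.write_midlines:
            name = f"{row['individual_id']}_trial{int(row['trial']):02d}.csv"
            write_midlines_csv(seq, mid_dir / name)
        wk = compute_wave_kinematics(seq, steady_tolerance=cfg.steady_tolerance)
        rows.append({
            "individual_id": row["individual_id"],
            "treatment": row["treatment"],
            "regeneration_pct": row["regeneration_pct"],
            "trial": int(row["trial"]),
            **dataclasses.asdict(wk),
        })
    return pd.DataFrame(rows)


def _analyze_csv(cfg: RunConfig) -> pd.DataFrame:
    """Kinematics for user-supplied midline CSVs (single- or multi-trial)."""
    df = pd.read_csv(cfg.midline_csv)
    meta_cols = [c for c in ("individual_id", "treatment", "regeneration_pct", "trial")
                 if c in df.columns]
    rows = []
    if meta_cols:
        group_keys = [c for c in ("individual_id", "trial") if c in meta_cols]
        groups = df.groupby(group_keys, dropna=False)
    else:
        groups = [((), df)]
    for key, sub in groups:
        n_p = sub["point_index"].nunique()
        frames = np.sort(sub["frame"].unique())
        xy = (sub.sort_values(["frame", "point_index"])[["x", "y"]]
              .to_numpy(float).reshape(len(frames), n_p, 2))
        from .core import MidlineSequence

        seq = MidlineSequence(xy, cfg.midline_frame_rate_hz, y_down=True)
        wk = compute_wave_kinematics(seq, steady_tolerance=cfg.steady_tolerance)
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        rows.append({**meta, **dataclasses.asdict(wk)})
    return pd.DataFrame(rows)


def analyze_trials(trials: pd.DataFrame, cfg: RunConfig | None = None) -> dict:
    """Run the statistics battery on a performance-annotated trial table."""
    cfg = cfg or RunConfig()
    report: dict = {"anova": [], "posthoc": {}, "assumptions": {},
                    "regressions": [], "mixed_model": None}
    has_groups = trials["treatment"].nunique() >= 2 if "treatment" in trials else False
    for resp in cfg.responses:
        if resp not in trials.columns or not has_groups:
            continue
        means = trials.groupby("individual_id", as_index=False).agg(
            {resp: "mean", "treatment": "first"})
        try:
            diag = check_parametric_assumptions(means, resp, alpha=cfg.alpha)
            report["assumptions"][resp] = {
                "normality_ok": diag.normality_ok,
                "homoscedastic": diag.homoscedastic,
                "levene_p": diag.levene_p,
                "shapiro": diag.shapiro.to_dict(orient="records"),
            }
            an = one_way_anova(means, resp)
            report["anova"].append(dataclasses.asdict(an))
            post = holm_sidak_posthoc(means, resp, alpha=cfg.alpha)
            report["posthoc"][resp] = post.to_dict(orient="records")
        except (SwimtrackError, ValueError) as exc:
            report["assumptions"][resp] = {"error": str(exc)}
    if "regeneration_pct" in trials.columns:
        for resp in cfg.responses:
            if resp not in trials.columns:
                continue
            try:
                reg = regress_on_regeneration(trials, resp)
                report["regressions"].append(dataclasses.asdict(reg))
            except SwimtrackError as exc:
                report["regressions"].append({"response": resp, "error": str(exc)})
        try:
            mm = mixed_model_speed(trials)
            report["mixed_model"] = {
                "fixed_effects": mm.fixed_effects.to_dict(orient="records"),
                "random_intercept_var": mm.random_intercept_var,
                "residual_var": mm.residual_var,
                "method": mm.method,
                "n_individuals": mm.n_individuals,
                "n_trials": mm.n_trials,
                "converged": mm.converged,
                "warning": mm.warning,
            }
        except (SwimtrackError, ValueError) as exc:
            report["mixed_model"] = {"error": str(exc)}
    return report


run_stats = analyze_trials


def _summary_text(trials: pd.DataFrame, report: dict) -> str:
    lines = ["swimtrack summary", "=" * 17, ""]
    if "treatment" in trials.columns:
        lines.append("Group means (individual means averaged within groups):")
        means = (trials.groupby(["treatment", "individual_id"]).mean(numeric_only=True)
                 .groupby("treatment").mean(numeric_only=True))
        cols = [c for c in DEFAULT_RESPONSES if c in means.columns]
        lines.append(means[cols].round(4).to_string())
        lines.append("")
    if report["anova"]:
        lines.append("One-way ANOVA across treatments (individual means):")
        for row in report["anova"]:
            lines.append(
                f"  {row['response']:18s} F({row['df_between']},{row['df_within']})"
                f"={row['f_stat']:.3f}  p={row['p_value']:.4f}"
            )
        lines.append("")
    if report["regressions"]:
        lines.append("Regressions on percent axon regeneration (transected only):")
        for row in report["regressions"]:
            if "error" in row:
                lines.append(f"  {row['response']:18s} [{row['error']}]")
            else:
                lines.append(
                    f"  {row['response']:18s} slope={row['slope']:+.4g}  "
                    f"F(1,{row['df_resid']})={row['f_stat']:.3f}  "
                    f"p={row['p_value']:.4f}  R2={row['r_squared']:.3f}"
                )
        lines.append("")
    mm = report.get("mixed_model")
    if mm and "error" not in mm:
        lines.append(
            f"Mixed model speed ~ frequency * regeneration "
            f"(+ 1|individual, {mm['method']}):"
        )
        for fe in mm["fixed_effects"]:
            lines.append(
                f"  {fe['term']:32s} {fe['estimate']:+.4g} (SE {fe['se']:.3g}) "
                f"p={fe['p']:.4f}"
            )
        lines.append(f"  random-intercept var: {mm['random_intercept_var']:.4g}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Artifacts: ``config.yaml`` (echo of the merged configuration),
    ``cohort.csv`` (simulated designs), ``kinematics.csv`` (one row per
    trial with QC flags), ``performance.csv`` (plus efficiency indices),
    ``stats.json``, ``summary.txt`` and ``provenance.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if config.simulate:
        trials = _simulate_trials(config, out)
    else:
        trials = _analyze_csv(config)
    trials.to_csv(out / "kinematics.csv", index=False, float_format=_FLOAT_FMT)

    perf = add_performance_columns(trials, config.amplitude_convention)
    perf.to_csv(out / "performance.csv", index=False, float_format=_FLOAT_FMT)

    report = analyze_trials(perf, config)
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    (out / "summary.txt").write_text(_summary_text(perf, report))

    provenance = {
        "swimtrack_version": __version__,
        "seed": config.seed,
        "stages": (["simulate"] if config.simulate else ["read_midlines"])
        + (["render", "track"] if (config.simulate and config.render) else [])
        + ["kinematics", "performance", "stats"],
        "row_counts": {"trials": int(len(trials))},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
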