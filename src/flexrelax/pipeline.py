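"""End-to-end orchestration: raw trials -> maps, curves and inference tables.

``analyze_trials`` consumes any iterable of :class:`MonopolarTrial` (from
disk or from the synthetic generator, which streams full-size cohorts
without materializing them) and runs: phase segmentation -> bipolar
derivation -> channel QC -> envelope -> per-channel offset detection and
onset map -> epoch-RMS amplitude profile -> repetition aggregation -> side
pooling -> both SS-ANOVA models -> pairwise contrasts.  Per-trial failures
are logged and skipped; the run fails only if an analysis group loses all
its subjects.

LBP subjects are assigned to the with-/without-FRP analysis subgroups from
the observed >50%-of-channels rule, mirroring how such cohorts are formed in
practice; controls keep their label.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import io as trial_io
from .amplitude import epoch_rms, normalize_profile
from .detect import DetectionConfig, OnsetMap, aggregate_repetitions, build_onset_map
from .errors import FlexRelaxError, PipelineError
from .grid import channel_anatomical_position
from .kinematics import SegmentationConfig, segment_phases
from .preprocess import FilterConfig, MonopolarTrial, QCConfig, derive_bipolar, envelope, quality_screen
from .ssanova import SplineDesign, contrast_difference, fit_ssanova
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_trials", "analyze_cohort",
           "run_simulate", "run_analyze", "run_report", "recovery_table"]

AMPLITUDE_PAIRS = [
    ("lbp_frp", "lbp_no_frp"),
    ("lbp_frp", "control"),
    ("lbp_no_frp", "control"),
]


@dataclass
class PipelineConfig:
    """Flat configuration for the CLI and orchestration layer."""

    input_dir: str = "cohort"
    output_dir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    ci_level: float = 0.95
    side_check_alpha: float = 0.05
    make_figures: bool = True
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise FlexRelaxError(f"ci_level must lie in (0, 1), got {self.ci_level}")

    def to_flat_dict(self) -> dict:
        def flatten(prefix, obj, out):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if dataclasses.is_dataclass(v) and not isinstance(v, type):
                    flatten(f"{prefix}{f.name}.", v, out)
                elif isinstance(v, (str, int, float, bool)) or v is None:
                    out[f"{prefix}{f.name}"] = v
                else:
                    out[f"{prefix}{f.name}"] = repr(v)
            return out

        return flatten("", self, {})


@dataclass
class AnalysisResult:
    """Everything the analysis computes, in memory."""

    classification: pd.DataFrame
    onset_data: pd.DataFrame
    amplitude_data: pd.DataFrame
    subject_maps: dict
    onset_fit: object | None
    onset_contrast: object | None
    amplitude_fit: object | None
    amplitude_contrasts: dict
    warnings: list[str]
    trial_log: pd.DataFrame


def _analysis_group(meta_group: str, frp_present: bool) -> str:
    if meta_group == "control":
        return "control"
    return "lbp_frp" if frp_present else "lbp_no_frp"


def _process_one(trial: MonopolarTrial, config: PipelineConfig):
    seg = segment_phases(trial.angle, trial.sampling_rate, config.segmentation)
    bt = derive_bipolar(trial, config.filter)
    bt = quality_screen(bt, seg, config.qc)
    env = envelope(bt)
    omap = build_onset_map(env, seg, config.detection)
    profile = normalize_profile(epoch_rms(bt, seg), bt, seg)
    return seg, omap, profile


def analyze_trials(
    trials: Iterable[MonopolarTrial], config: PipelineConfig | None = None
) -> AnalysisResult:
    """Run the full analysis over an iterable of trials."""
    config = config or PipelineConfig()
    per_rep: dict[tuple, list] = {}
    groups: dict[tuple, str] = {}
    log_rows = []
    caught: list[str] = []

    for trial in trials:
        key = (trial.meta.subject, trial.meta.side)
        try:
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                seg, omap, profile = _process_one(trial, config)
            for w in wrec:
                caught.append(f"{trial.meta.key()}: {w.message}")
            per_rep.setdefault(key, []).append((omap, profile.epochs))
            groups[key] = trial.meta.group
            log_rows.append(
                {
                    "subject": trial.meta.subject,
                    "group": trial.meta.group,
                    "side": trial.meta.side,
                    "repetition": trial.meta.repetition,
                    "status": "ok",
                    "n_excluded_channels": len(omap.excluded),
                    "flexion_duration_s": seg.flexion_duration,
                    "max_flexion_angle_deg": seg.max_flexion_angle,
                }
            )
        except FlexRelaxError as exc:
            caught.append(f"{trial.meta.key()}: {exc}")
            log_rows.append(
                {
                    "subject": trial.meta.subject,
                    "group": trial.meta.group,
                    "side": trial.meta.side,
                    "repetition": trial.meta.repetition,
                    "status": f"failed: {exc}",
                    "n_excluded_channels": np.nan,
                    "flexion_duration_s": np.nan,
                    "max_flexion_angle_deg": np.nan,
                }
            )

    if not per_rep:
        raise PipelineError("no trial could be analyzed")

    # aggregate repetitions per subject/side
    subject_maps: dict[tuple, OnsetMap] = {}
    subject_profiles: dict[tuple, np.ndarray] = {}
    class_rows = []
    for key, items in sorted(per_rep.items()):
        maps = [m for m, _ in items]
        profs = [p for _, p in items if p is not None]
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            agg, prof = aggregate_repetitions(maps, profs)
        for w in wrec:
            caught.append(f"{key}: {w.message}")
        subject_maps[key] = agg
        if prof is not None:
            subject_profiles[key] = prof
        class_rows.append(
            {
                "subject": key[0],
                "group": groups[key],
                "side": key[1],
                "frp_present": agg.frp_present,
                "fraction_channels_with_frp": agg.fraction_channels_with_frp,
                "mean_onset_pct": agg.mean_onset_pct,
                "n_repetitions": len(maps),
            }
        )
    classification = pd.DataFrame(class_rows)

    # subject-level FRP status: present on both sides -> present (majority;
    # single-sided recordings use that side)
    subj_status = (
        classification.groupby("subject")
        .agg(group=("group", "first"), frp_present=("frp_present", lambda s: s.mean() >= 0.5))
        .reset_index()
    )
    subj_status["analysis_group"] = [
        _analysis_group(g, p) for g, p in zip(subj_status["group"], subj_status["frp_present"])
    ]
    classification = classification.merge(
        subj_status[["subject", "analysis_group"]], on="subject"
    )

    # side-difference check (paired on subjects recorded on both sides)
    wide = classification.pivot_table(
        index="subject", columns="side", values="mean_onset_pct"
    )
    if wide.shape[1] == 2:
        both = wide.dropna()
        if len(both) >= 3:
            tt = sstats.ttest_rel(both.iloc[:, 0], both.iloc[:, 1])
            if tt.pvalue < config.side_check_alpha:
                msg = (
                    f"side difference in mean onset (paired p={tt.pvalue:.3f} < "
                    f"{config.side_check_alpha}); pooling sides regardless"
                )
                warnings.warn(msg, stacklevel=2)
                caught.append(msg)

    # long-format onset table (per subject x side x channel, FRP subjects only)
    onset_rows = []
    for (subject, side), amap in subject_maps.items():
        g = subj_status.loc[subj_status["subject"] == subject, "analysis_group"].iloc[0]
        if g == "lbp_no_frp" or not amap.frp_present:
            continue
        for i, ch in enumerate(amap.channels):
            if i in amap.excluded or not ch.present:
                continue
            onset_rows.append(
                {
                    "subject": subject,
                    "group": g,
                    "side": side,
                    "lattice_row": ch.lattice_position[0],
                    "lattice_col": ch.lattice_position[1],
                    "onset_pct": ch.onset_pct,
                }
            )
    onset_data = pd.DataFrame(onset_rows)
    if not onset_data.empty:
        layout = config.synthetic.layout
        ied = layout.inter_electrode_distance
        onset_data["x_mm"] = onset_data["lattice_col"] * ied
        onset_data["y_mm"] = (onset_data["lattice_row"] + 0.5) * ied

    # amplitude table: pool sides (average profiles), one row per subject x epoch
    amp_rows = []
    for subject in subj_status["subject"]:
        profs = [p for (s, _), p in subject_profiles.items() if s == subject]
        if not profs:
            continue
        m = min(len(p) for p in profs)
        prof = np.mean([p[:m] for p in profs], axis=0)
        g = subj_status.loc[subj_status["subject"] == subject, "analysis_group"].iloc[0]
        for e, v in enumerate(prof):
            amp_rows.append(
                {
                    "subject": subject,
                    "group": g,
                    "epoch_index": e + 1,
                    "time_s": e + 0.5,
                    "phase": "flexion" if e < 4 else "mvf",
                    "normalized_pct": v,
                }
            )
    amplitude_data = pd.DataFrame(amp_rows)

    # ---- inference -------------------------------------------------------
    onset_fit = onset_contrast = None
    if not onset_data.empty:
        counts = onset_data.groupby("group")["subject"].nunique()
        if set(counts.index) >= {"control", "lbp_frp"} and (counts >= 2).all():
            factors = ("group", "side") if onset_data["side"].nunique() > 1 else ("group",)
            design = SplineDesign(
                response="onset_pct",
                axes=("x_mm", "y_mm"),
                kind="thin_plate",
                factors=factors,
                interaction_factors=("group",),
                subject="subject",
            )
            onset_fit = fit_ssanova(onset_data, design)
            onset_contrast = contrast_difference(
                onset_fit, "lbp_frp", "control", factor="group", ci_level=config.ci_level
            )
        else:
            caught.append(
                "onset model skipped: need >=2 subjects in each of control and lbp_frp "
                f"(have {counts.to_dict()})"
            )
    else:
        caught.append("onset model skipped: no subjects exhibit the FRP")

    amplitude_fit = None
    amplitude_contrasts: dict = {}
    if not amplitude_data.empty:
        counts = amplitude_data.groupby("group")["subject"].nunique()
        present = [g for g in counts.index if counts[g] >= 2]
        if len(present) >= 2:
            sub = amplitude_data[amplitude_data["group"].isin(present)]
            design = SplineDesign(
                response="normalized_pct",
                axes=("time_s",),
                kind="cubic",
                factors=("group",),
                subject="subject",
            )
            amplitude_fit = fit_ssanova(sub, design)
            for a, b in AMPLITUDE_PAIRS:
                if a in present and b in present:
                    amplitude_contrasts[(a, b)] = contrast_difference(
                        amplitude_fit, a, b, factor="group", ci_level=config.ci_level
                    )
        else:
            caught.append(f"amplitude model skipped: fewer than 2 groups with >=2 subjects")

    return AnalysisResult(
        classification=classification,
        onset_data=onset_data,
        amplitude_data=amplitude_data,
        subject_maps=subject_maps,
        onset_fit=onset_fit,
        onset_contrast=onset_contrast,
        amplitude_fit=amplitude_fit,
        amplitude_contrasts=amplitude_contrasts,
        warnings=caught,
        trial_log=pd.DataFrame(log_rows),
    )


def analyze_cohort(
    cohort: SyntheticCohort, config: PipelineConfig | None = None
) -> AnalysisResult:
    """Analyze a synthetic cohort (streams trials; does not materialize)."""
    return analyze_trials(cohort.iter_trials(), config)


def recovery_table(result: AnalysisResult, cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-subject estimated vs true mean onset (truth-aware cohorts only)."""
    truth = (
        cohort.channel_truth.groupby("subject")
        .agg(true_mean_onset_pct=("true_onset_pct", "mean"), group=("group", "first"))
        .reset_index()
    )
    est = (
        result.classification.groupby("subject")["mean_onset_pct"].mean().rename("est_mean_onset_pct")
    )
    out = truth.merge(est, on="subject", how="inner")
    out["error_pct"] = out["est_mean_onset_pct"] - out["true_mean_onset_pct"]
    return out


# ---------------------------------------------------------------------------
# disk-level commands


def run_simulate(config: PipelineConfig) -> Path:
    """Generate a synthetic cohort and write it in the on-disk trial format."""
    outdir = Path(config.input_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.synthetic, materialize=False)
    n = 0
    for trial in cohort.iter_trials():
        trial_io.write_trial(outdir, trial)
        n += 1
    cohort.subjects.to_csv(outdir / "truth_subjects.csv", index=False)
    cohort.channel_truth.to_csv(outdir / "truth_onsets.csv", index=False)
    cohort.phase_truth.to_csv(outdir / "truth_phases.csv", index=False)
    manifest = {
        "command": "simulate",
        "n_trials": n,
        "seed": config.synthetic.seed,
        "config": config.to_flat_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def _write_contrast(path: Path, contrast) -> None:
    grid = np.atleast_2d(contrast.grid)
    if grid.shape[0] != len(contrast.difference):
        grid = grid.T
    cols = {f"axis_{i}": grid[:, i] for i in range(grid.shape[1])}
    pd.DataFrame(
        {**cols, "difference": contrast.difference,
         "ci_lower": contrast.ci_lower, "ci_upper": contrast.ci_upper}
    ).to_csv(path, index=False)


def run_analyze(config: PipelineConfig) -> AnalysisResult:
    """Analyze a cohort on disk; write tables, figures and a run manifest."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = (trial_io.read_trial(p) for p in trial_io.iter_trial_files(indir))
    result = analyze_trials(trials, config)

    result.classification.to_csv(outdir / "classification.csv", index=False)
    result.onset_data.to_csv(outdir / "onset_map.csv", index=False)
    result.amplitude_data.to_csv(outdir / "amplitude_profiles.csv", index=False)
    result.trial_log.to_csv(outdir / "trial_log.csv", index=False)
    if result.onset_contrast is not None:
        _write_contrast(outdir / "onset_contrast.csv", result.onset_contrast)
    for (a, b), c in result.amplitude_contrasts.items():
        _write_contrast(outdir / f"amplitude_contrast_{a}_vs_{b}.csv", c)

    summary = {
        "command": "analyze",
        "warnings": result.warnings,
        "onset_model": None
        if result.onset_fit is None
        else {
            "r_squared": result.onset_fit.r_squared,
            "lambdas": result.onset_fit.smoothing_parameters,
            "mean_delay_pct": result.onset_contrast.mean_difference,
            "delay_ci": list(result.onset_contrast.mean_ci),
            "significant": result.onset_contrast.significant,
        },
        "amplitude_model": None
        if result.amplitude_fit is None
        else {
            "r_squared": result.amplitude_fit.r_squared,
            "lambdas": result.amplitude_fit.smoothing_parameters,
            "contrasts": {
                f"{a}_vs_{b}": {
                    "mean_difference_pct": c.mean_difference,
                    "ci": list(c.mean_ci),
                    "significant": c.significant,
                }
                for (a, b), c in result.amplitude_contrasts.items()
            },
        },
        "config": config.to_flat_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    if config.make_figures:
        _make_figures(result, config, outdir)
    return result


def _make_figures(result: AnalysisResult, config: PipelineConfig, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout = config.synthetic.layout
    if not result.onset_data.empty:
        groups = sorted(result.onset_data["group"].unique())
        fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 5), squeeze=False)
        for ax, g in zip(axes[0], groups):
            sub = result.onset_data[result.onset_data["group"] == g]
            grid = np.full((layout.n_rows - 1, layout.n_cols), np.nan)
            means = sub.groupby(["lattice_row", "lattice_col"])["onset_pct"].mean()
            for (r, c), v in means.items():
                grid[int(r), int(c)] = v
            im = ax.imshow(grid, origin="lower", aspect="equal", cmap="viridis")
            ax.set_title(f"{g}: FRP onset (%)")
            ax.set_xlabel("column")
            ax.set_ylabel("row (caudal -> cranial)")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(outdir / "onset_maps.png", dpi=110)
        plt.close(fig)

    if not result.amplitude_data.empty:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for g, sub in result.amplitude_data.groupby("group"):
            stat = sub.groupby("time_s")["normalized_pct"].agg(["mean", "std"])
            ax.errorbar(stat.index, stat["mean"], yerr=stat["std"], label=g, capsize=3)
        ax.set_xlabel("time (s, flexion + MVF)")
        ax.set_ylabel("EMG amplitude (% of extension peak)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "amplitude_curves.png", dpi=110)
        plt.close(fig)

    for (a, b), c in result.amplitude_contrasts.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.atleast_2d(c.grid).reshape(-1)
        ax.plot(x, c.difference, color="k")
        ax.fill_between(x, c.ci_lower, c.ci_upper, alpha=0.3)
        ax.axhline(0.0, color="r", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"amplitude difference {a} - {b} (%)")
        fig.tight_layout()
        fig.savefig(outdir / f"amplitude_contrast_{a}_vs_{b}.png", dpi=110)
        plt.close(fig)


def run_report(config: PipelineConfig) -> Path:
    """Summarize an analysis directory into a plain-text report."""
    outdir = Path(config.output_dir)
    cls_path = outdir / "classification.csv"
    if not cls_path.exists():
        raise FlexRelaxError(f"missing analysis outputs: {cls_path} not found (run analyze first)")
    cls = pd.read_csv(cls_path)
    subj = cls.groupby("subject").agg(
        group=("group", "first"),
        analysis_group=("analysis_group", "first"),
        frp_present=("frp_present", lambda s: s.mean() >= 0.5),
    )
    lbp = subj[subj["group"] != "control"]
    lines = ["# Flexion-relaxation analysis report", ""]
    lines.append(f"subjects: {len(subj)} ({(subj['group'] == 'control').sum()} control, {len(lbp)} LBP)")
    counts = subj.groupby("analysis_group").size()
    lines.append("analysis groups: " + ", ".join(f"{g}={n}" for g, n in counts.items()))
    if len(lbp):
        prev = 100.0 * lbp["frp_present"].mean()
        lines.append(f"FRP prevalence among LBP: {prev:.1f}%")
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        om = manifest.get("onset_model")
        if om:
            lines.append(
                f"onset delay (lbp_frp - control): {om['mean_delay_pct']:.1f}% "
                f"(95% CI {om['delay_ci'][0]:.1f} to {om['delay_ci'][1]:.1f}), "
                f"significant={om['significant']}, model R^2={100 * om['r_squared']:.1f}%"
            )
        am = manifest.get("amplitude_model")
        if am:
            lines.append(f"amplitude model R^2={100 * am['r_squared']:.1f}%")
            for name, c in am.get("contrasts", {}).items():
                lines.append(
                    f"  {name}: {c['mean_difference_pct']:.1f}% "
                    f"(95% CI {c['ci'][0]:.1f} to {c['ci'][1]:.1f}), significant={c['significant']}"
                )
    truth_path = Path(config.input_dir) / "truth_onsets.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        t = truth.groupby("subject")["true_onset_pct"].mean().rename("true_mean_onset_pct")
        est = cls.groupby("subject")["mean_onset_pct"].mean().rename("est_mean_onset_pct")
        rec = pd.concat([t, est], axis=1, join="inner").dropna()
        rec["error_pct"] = rec["est_mean_onset_pct"] - rec["true_mean_onset_pct"]
        rec.to_csv(outdir / "recovery.csv")
        lines.append(
            f"onset recovery over {len(rec)} subjects: bias={rec['error_pct'].mean():.2f}%, "
            f"RMSE={np.sqrt((rec['error_pct'] ** 2).mean()):.2f}%"
        )
    report = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(report)
    return outdir / "report.md"
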