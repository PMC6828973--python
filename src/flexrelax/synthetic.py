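"""Synthetic HDEMG cohort generator.

Emulates the acquisition the analysis expects: per subject, side and
repetition, a 64-electrode monopolar grid recording at 2048 Hz plus an
electrogoniometer trace for a trapezoidal trunk-flexion task (quiet standing,
4 s flexion, 8 s sustained full flexion, 4 s extension).

Signal model
------------
Each electrode carries band-limited Gaussian carrier noise (default
20-350 Hz) multiplied by a piecewise amplitude envelope.  Electrodes on one
grid share a common source mixed with per-electrode noise (weight
``spatial_mixing``), so bipolar derivation genuinely cancels a common-mode
component.  The envelope sits at a tonic postural level during quiet
standing, rises at movement onset, and -- for subjects who exhibit the
flexion-relaxation phenomenon -- drops back over a smooth ~150 ms sigmoid at
a channel-specific offset placed on the flexion-angle axis:

    offset(electrode) = subject mean + gradient * (row - centre) + jitter

with the gradient making cranial channels relax later.  Subjects of the
``lbp_no_frp`` group never relax.  Extension re-activates every channel at
the cohort's largest amplitude, so the amplitude-normalization reference
falls in the extension phase.

Ground truth (per-channel true offsets on the bipolar lattice, true phase
boundaries, injected faults) is recorded so downstream stages can be tested
by parameter recovery.  A bipolar channel is silent only once both of its
electrodes are, so its recorded true offset is the later of the two
electrode offsets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .errors import ConfigError
from .grid import GridLayout, enumerate_bipolar_channels
from .preprocess import MonopolarTrial, TrialMeta

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort", "inject_channel_faults"]

GROUPS = ("control", "lbp_frp", "lbp_no_frp")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions the pipeline targets: group sizes
    14 controls / 9 LBP with FRP / 5 LBP without FRP, 2048 Hz sampling, a
    4 s / 8 s / 4 s flexion task preceded by 2 s of quiet standing, control
    relaxation around 55% of trunk flexion versus 68% for the delayed LBP
    subgroup (an injected 13-point delay), and a maximal flexion angle of
    91 +/- 11 degrees.
    """

    n_per_group: tuple[int, int, int] = (14, 9, 5)
    sampling_rate: float = 2048.0
    phase_durations: tuple[float, float, float] = (4.0, 8.0, 4.0)
    baseline_duration: float = 2.0
    true_onset_mean: dict = field(
        default_factory=lambda: {"control": 55.0, "lbp_frp": 68.0}
    )
    onset_between_subject_sd: float = 4.0
    onset_channel_jitter_sd: float = 1.0
    onset_spatial_gradient: dict = field(
        default_factory=lambda: {"control": 0.0, "lbp_frp": 0.5}
    )
    envelope_amplitude: float = 1.0
    baseline_amplitude: float = 0.1
    relaxation_depth: float = 1.0
    extension_boost: float = 1.3
    noise_bandwidth: tuple[float, float] = (20.0, 350.0)
    spatial_mixing: float = 0.5
    max_flexion_angle_mean: float = 91.0
    max_flexion_angle_sd: float = 11.0
    n_repetitions: int = 3
    sides: tuple[str, ...] = ("left", "right")
    corner_smooth_s: float = 0.25
    deactivation_s: float = 0.15
    layout: GridLayout = field(default_factory=GridLayout)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be positive, got {self.n_per_group}")
        positive = {
            "sampling_rate": self.sampling_rate,
            "baseline_duration": self.baseline_duration,
            "envelope_amplitude": self.envelope_amplitude,
            "baseline_amplitude": self.baseline_amplitude,
            "relaxation_depth": self.relaxation_depth,
            "n_repetitions": self.n_repetitions,
            "max_flexion_angle_mean": self.max_flexion_angle_mean,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if any(d <= 0 for d in self.phase_durations):
            raise ConfigError("phase durations must be positive")
        for g, m in self.true_onset_mean.items():
            if not 0 < m < 100:
                raise ConfigError(f"true_onset_mean[{g}]={m} outside (0, 100)")
        lo, hi = self.noise_bandwidth
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ConfigError(f"noise_bandwidth {self.noise_bandwidth} infeasible at fs")
        if not 0 <= self.spatial_mixing < 1:
            raise ConfigError("spatial_mixing must lie in [0, 1)")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + sum(self.phase_durations)


# ---------------------------------------------------------------------------
# cohort plan: all per-subject / per-channel random draws, no signal blocks


def _subject_table(config: SyntheticConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    prefixes = {"control": "ctrl", "lbp_frp": "frp", "lbp_no_frp": "nofrp"}
    rows = []
    for group, n in zip(GROUPS, config.n_per_group):
        for i in range(n):
            max_angle = float(
                np.clip(
                    rng.normal(config.max_flexion_angle_mean, config.max_flexion_angle_sd),
                    45.0,
                    140.0,
                )
            )
            if group in config.true_onset_mean:
                onset = float(
                    np.clip(
                        rng.normal(
                            config.true_onset_mean[group], config.onset_between_subject_sd
                        ),
                        15.0,
                        92.0,
                    )
                )
            else:
                onset = np.nan
            rows.append(
                {
                    "subject": f"{prefixes[group]}{i + 1:02d}",
                    "group": group,
                    "max_flexion_angle": max_angle,
                    "onset_mean_pct": onset,
                }
            )
    return pd.DataFrame(rows)


def _electrode_onsets(
    config: SyntheticConfig, subjects: pd.DataFrame
) -> tuple[dict, pd.DataFrame]:
    """Per-electrode true offsets per subject x side, plus the bipolar-lattice
    truth table recorded for recovery tests."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    layout = config.layout
    centre = (layout.n_rows - 1) / 2.0
    channels = enumerate_bipolar_channels(layout)
    per_side: dict[tuple[str, str], np.ndarray | None] = {}
    truth_rows = []
    for _, subj in subjects.iterrows():
        grad = config.onset_spatial_gradient.get(subj["group"], 0.0)
        for side in config.sides:
            if np.isnan(subj["onset_mean_pct"]):
                per_side[(subj["subject"], side)] = None
                continue
            onsets = np.full((layout.n_rows, layout.n_cols), np.nan)
            for r in range(layout.n_rows):
                for c in range(layout.n_cols):
                    if layout.has_electrode(r, c):
                        onsets[r, c] = (
                            subj["onset_mean_pct"]
                            + grad * (r - centre)
                            + rng.normal(0.0, config.onset_channel_jitter_sd)
                        )
            onsets = np.clip(onsets, 2.0, 98.0)
            per_side[(subj["subject"], side)] = onsets
            for ch in channels:
                r0, r1 = ch.row_pair
                truth_rows.append(
                    {
                        "subject": subj["subject"],
                        "group": subj["group"],
                        "side": side,
                        "lattice_row": r0,
                        "lattice_col": ch.column,
                        "true_onset_pct": max(onsets[r0, ch.column], onsets[r1, ch.column]),
                    }
                )
    return per_side, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# signal synthesis


def _hann_smooth(x: np.ndarray, width_n: int) -> np.ndarray:
    if width_n < 3:
        return x
    if width_n % 2 == 0:
        width_n += 1
    w = np.hanning(width_n)
    w /= w.sum()
    pad = width_n // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, w, mode="valid")


def _angle_trace(config: SyntheticConfig, max_angle: float) -> tuple[np.ndarray, dict]:
    fs = config.sampling_rate
    d_flex, d_mvf, d_ext = config.phase_durations
    t0 = config.baseline_duration
    n = int(round(config.total_duration * fs))
    t = np.arange(n) / fs
    trap = np.interp(
        t,
        [0.0, t0, t0 + d_flex, t0 + d_flex + d_mvf, t0 + d_flex + d_mvf + d_ext],
        [0.0, 0.0, max_angle, max_angle, 0.0],
    )
    angle = _hann_smooth(trap, int(round(config.corner_smooth_s * fs)))
    bounds = {
        "t_flex_start": t0,
        "t_flex_end": t0 + d_flex,
        "t_ext_start": t0 + d_flex + d_mvf,
        "t_ext_end": t0 + d_flex + d_mvf + d_ext,
    }
    return angle, bounds


def _band_noise(rng: np.random.Generator, n: int, k: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """k columns of unit-variance noise band-limited to ``band``."""
    sos = sps.butter(6, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n, k)), axis=0)
    x /= np.maximum(x.std(axis=0), 1e-12)
    return x


def _electrode_gains(
    config: SyntheticConfig,
    angle: np.ndarray,
    bounds: dict,
    max_angle: float,
    onsets: np.ndarray | None,
) -> np.ndarray:
    """samples x electrodes envelope-gain block."""
    fs = config.sampling_rate
    layout = config.layout
    n = angle.size
    t = np.arange(n) / fs
    tau = config.deactivation_s / 8.0
    A = config.envelope_amplitude
    b = config.baseline_amplitude
    low = b * config.relaxation_depth
    ext_amp = config.extension_boost * A

    cols = []
    i0 = int(bounds["t_flex_start"] * fs)
    i1 = int(bounds["t_flex_end"] * fs)
    rise_seg = angle[i0:i1]
    for c in range(layout.n_cols):
        for r in range(layout.n_rows):
            if not layout.has_electrode(r, c):
                continue
            g = b + (A - b) * expit((t - bounds["t_flex_start"]) / tau)
            if onsets is not None:
                # map the offset from the angle axis to time via the rising limb
                target = onsets[r, c] / 100.0 * max_angle
                j = int(np.searchsorted(rise_seg, target))
                t_off = (i0 + min(j, rise_seg.size - 1)) / fs
                pre = b + (A - b) * expit((t_off - bounds["t_flex_start"]) / tau)
                g = g + (low - pre) * expit((t - t_off) / tau)
                level_before_ext = low
            else:
                level_before_ext = A
            g = g + (ext_amp - level_before_ext) * expit((t - bounds["t_ext_start"]) / tau)
            g = g + (b - ext_amp) * expit((t - bounds["t_ext_end"]) / tau)
            cols.append(g)
    order = np.argsort(
        [
            layout.electrode_index(r, c)
            for c in range(layout.n_cols)
            for r in range(layout.n_rows)
            if layout.has_electrode(r, c)
        ]
    )
    return np.stack(cols, axis=1)[:, order]


def _generate_trial(
    config: SyntheticConfig,
    subject: pd.Series,
    side: str,
    repetition: int,
    onsets: np.ndarray | None,
    trial_index: int,
) -> MonopolarTrial:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2, trial_index))
    )
    fs = config.sampling_rate
    angle, bounds = _angle_trace(config, subject["max_flexion_angle"])
    n = angle.size
    n_elec = config.layout.n_electrodes
    noise = _band_noise(rng, n, n_elec + 1, fs, config.noise_bandwidth)
    shared, per_ch = noise[:, :1], noise[:, 1:]
    w = config.spatial_mixing
    carrier = np.sqrt(w) * shared + np.sqrt(1.0 - w) * per_ch
    gains = _electrode_gains(config, angle, bounds, subject["max_flexion_angle"], onsets)
    return MonopolarTrial(
        signals=(gains * carrier).astype(np.float32),
        sampling_rate=fs,
        angle=angle,
        layout=config.layout,
        meta=TrialMeta(
            subject=subject["subject"], group=subject["group"], side=side, repetition=repetition
        ),
    )


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``trials`` materializes every trial in memory (fine for small
    configurations); :meth:`iter_trials` regenerates them lazily and
    deterministically, which is how the pipeline consumes full-size cohorts.
    """

    config: SyntheticConfig
    subjects: pd.DataFrame
    channel_truth: pd.DataFrame
    phase_truth: pd.DataFrame
    fault_truth: pd.DataFrame
    _onsets: dict = field(repr=False, default_factory=dict)
    _trials: list[MonopolarTrial] | None = field(repr=False, default=None)

    def _trial_specs(self) -> list[tuple[pd.Series, str, int, int]]:
        specs = []
        idx = 0
        for _, subj in self.subjects.iterrows():
            for side in self.config.sides:
                for rep in range(self.config.n_repetitions):
                    specs.append((subj, side, rep, idx))
                    idx += 1
        return specs

    @property
    def n_trials(self) -> int:
        return len(self.subjects) * len(self.config.sides) * self.config.n_repetitions

    def iter_trials(self) -> Iterator[MonopolarTrial]:
        if self._trials is not None:
            yield from self._trials
            return
        for subj, side, rep, idx in self._trial_specs():
            yield _generate_trial(
                self.config, subj, side, rep, self._onsets[(subj["subject"], side)], idx
            )

    @property
    def trials(self) -> list[MonopolarTrial]:
        if self._trials is None:
            self._trials = list(self.iter_trials())
        return self._trials


def generate_cohort(config: SyntheticConfig, materialize: bool = True) -> SyntheticCohort:
    """Generate a cohort (bit-reproducible for a fixed ``config.seed``)."""
    subjects = _subject_table(config)
    onsets, channel_truth = _electrode_onsets(config, subjects)
    phase_rows = []
    for _, subj in subjects.iterrows():
        _, bounds = _angle_trace(config, subj["max_flexion_angle"])
        for side in config.sides:
            for rep in range(config.n_repetitions):
                phase_rows.append(
                    {"subject": subj["subject"], "side": side, "repetition": rep, **bounds}
                )
    cohort = SyntheticCohort(
        config=config,
        subjects=subjects,
        channel_truth=channel_truth,
        phase_truth=pd.DataFrame(phase_rows),
        fault_truth=pd.DataFrame(
            columns=["subject", "side", "repetition", "electrode_index", "fault"]
        ),
        _onsets=onsets,
    )
    if materialize:
        _ = cohort.trials
    return cohort


def inject_channel_faults(
    cohort: SyntheticCohort, fraction: float, seed: int = 0
) -> SyntheticCohort:
    """Corrupt a fraction of monopolar electrodes per grid.

    ``floor(fraction * n_electrodes)`` electrodes per trial are replaced with
    either near-zero signal (lost skin contact) or a large sub-5 Hz movement
    artefact, drawn 50/50.  The corrupted electrodes are recorded in
    ``fault_truth``.  Materializes the cohort.
    """
    if not 0 <= fraction < 1:
        raise ConfigError(f"fraction must lie in [0, 1), got {fraction}")
    if fraction == 0:
        return cohort
    rng = np.random.default_rng(seed)
    config = cohort.config
    n_bad = int(fraction * config.layout.n_electrodes)
    new_trials = []
    fault_rows = []
    for trial in cohort.iter_trials():
        trial = copy.deepcopy(trial)
        sig = np.asarray(trial.signals, dtype=np.float32)
        bad = rng.choice(config.layout.n_electrodes, size=n_bad, replace=False)
        for e in bad:
            kind = "near_zero" if rng.random() < 0.5 else "artefact"
            if kind == "near_zero":
                sig[:, e] = 1e-6 * rng.standard_normal(sig.shape[0])
            else:
                sos = sps.butter(4, 4.0 / (config.sampling_rate / 2), btype="low", output="sos")
                drift = sps.sosfiltfilt(sos, rng.standard_normal(sig.shape[0]))
                drift /= max(drift.std(), 1e-12)
                sig[:, e] = 5.0 * config.envelope_amplitude * drift
            fault_rows.append(
                {
                    "subject": trial.meta.subject,
                    "side": trial.meta.side,
                    "repetition": trial.meta.repetition,
                    "electrode_index": int(e),
                    "fault": kind,
                }
            )
        trial.signals = sig
        new_trials.append(trial)
    return replace(
        cohort,
        fault_truth=pd.DataFrame(fault_rows),
        _trials=new_trials,
    )
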