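"""Channel QC, monopolar-to-bipolar derivation, band-pass filtering, envelopes.

The 64 monopolar signals of a grid are band-pass filtered (default 4th-order
Butterworth, 20-350 Hz, applied forward-backward so filtering is zero-phase
and timing estimates are unbiased) and differenced along columns to produce
the 59 single-differential (bipolar) channels.  Channels with poor signal
quality are flagged -- never deleted -- so downstream spatial maps can show
the holes.  Amplitude envelopes are obtained by full-wave rectification
followed by a zero-phase 50 Hz low-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InputError, PipelineError
from .grid import BipolarChannelIndex, GridLayout, enumerate_bipolar_channels
from .kinematics import PhaseSegmentation

__all__ = [
    "TrialMeta",
    "MonopolarTrial",
    "BipolarTrial",
    "EnvelopeTrial",
    "FilterConfig",
    "QCConfig",
    "bandpass_filter",
    "derive_bipolar",
    "quality_screen",
    "envelope",
]


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one recorded repetition."""

    subject: str
    group: str
    side: str
    repetition: int

    def key(self) -> tuple[str, str, str, int]:
        return (self.subject, self.group, self.side, self.repetition)


@dataclass
class MonopolarTrial:
    """One repetition as recorded: samples x electrodes block plus angle trace."""

    signals: np.ndarray
    sampling_rate: float
    angle: np.ndarray
    layout: GridLayout
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.signals.ndim != 2:
            raise InputError("signals must be a samples x channels block")
        if self.signals.shape[0] != self.angle.shape[0]:
            raise InputError(
                f"signals ({self.signals.shape[0]} samples) and angle "
                f"({self.angle.shape[0]}) disagree"
            )
        if self.signals.shape[1] != self.layout.n_electrodes:
            raise InputError(
                f"expected {self.layout.n_electrodes} electrode channels, "
                f"got {self.signals.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]


@dataclass
class BipolarTrial:
    """Band-passed bipolar channels with QC flags.

    ``signals`` holds the filtered bipolar block; ``raw_signals`` the
    unfiltered differences (kept for the low-frequency artefact check).
    ``excluded`` maps channel index -> reason code; flagged channels stay in
    the block.
    """

    signals: np.ndarray
    channels: list[BipolarChannelIndex]
    sampling_rate: float
    angle: np.ndarray
    meta: TrialMeta
    layout: GridLayout
    raw_signals: np.ndarray | None = None
    monopolar_signals: np.ndarray | None = None
    electrode_pairs: np.ndarray | None = None
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signals.shape[1] != len(self.channels):
            raise InputError("signal block does not match channel list")

    @property
    def included(self) -> list[int]:
        return [i for i in range(len(self.channels)) if i not in self.excluded]


@dataclass
class EnvelopeTrial:
    """Rectified, low-pass-filtered amplitude envelopes (non-negative)."""

    envelopes: np.ndarray
    source: BipolarTrial
    filter_spec: dict[str, Any]

    @property
    def sampling_rate(self) -> float:
        return self.source.sampling_rate


@dataclass(frozen=True)
class FilterConfig:
    """Band-pass specification for the monopolar signals.

    The high cutoff is capped just below Nyquist so the same configuration is
    valid at reduced sampling rates.
    """

    low_hz: float = 20.0
    high_hz: float = 350.0
    order: int = 4

    def effective_band(self, fs: float) -> tuple[float, float]:
        high = min(self.high_hz, 0.45 * fs)
        if high <= self.low_hz:
            raise ConfigError(
                f"band [{self.low_hz}, {self.high_hz}] Hz infeasible at fs={fs} Hz"
            )
        return (self.low_hz, high)


@dataclass(frozen=True)
class QCConfig:
    """Channel-exclusion thresholds.

    snr_min : minimum ratio of flexion-window RMS to baseline-window RMS of
        the band-passed bipolar signal.
    artefact_max : maximum fraction of raw-signal power below ``artefact_hz``
        over the movement window.
    dead_electrode_frac : a monopolar electrode whose movement-window RMS is
        below this fraction of the grid's median electrode RMS is treated as
        a lost skin contact; both bipolar channels touching it are flagged
        (the surviving neighbour makes such channels look deceptively clean
        at the bipolar level).
    """

    snr_min: float = 3.0
    artefact_max: float = 0.5
    artefact_hz: float = 20.0
    dead_electrode_frac: float = 0.1


def bandpass_filter(x: np.ndarray, fs: float, config: FilterConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    cfg = config or FilterConfig()
    low, high = cfg.effective_band(fs)
    sos = sps.butter(cfg.order, [low / (fs / 2), high / (fs / 2)], btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def derive_bipolar(
    trial: MonopolarTrial, filter_config: FilterConfig | None = None
) -> BipolarTrial:
    """Band-pass the monopolar block, then form along-column adjacent differences.

    Differences are taken caudal-minus-cranial; output channel order follows
    :func:`flexrelax.grid.enumerate_bipolar_channels`.
    """
    fs = trial.sampling_rate
    if trial.n_samples < fs:
        raise InputError("trial shorter than 1 s; too short for stable filtering")
    channels = enumerate_bipolar_channels(trial.layout)
    filtered = bandpass_filter(trial.signals, fs, filter_config)
    lo = np.array([trial.layout.electrode_index(r0, ch.column) for ch in channels for r0 in [ch.row_pair[0]]])
    hi = np.array([trial.layout.electrode_index(ch.row_pair[1], ch.column) for ch in channels])
    raw = np.asarray(trial.signals, dtype=float)
    return BipolarTrial(
        signals=filtered[:, lo] - filtered[:, hi],
        raw_signals=raw[:, lo] - raw[:, hi],
        monopolar_signals=raw,
        electrode_pairs=np.column_stack([lo, hi]),
        channels=channels,
        sampling_rate=fs,
        angle=trial.angle,
        meta=trial.meta,
        layout=trial.layout,
    )


def _window_rms(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x[lo:hi]), axis=0))


def quality_screen(
    trial: BipolarTrial, seg: PhaseSegmentation, config: QCConfig | None = None
) -> BipolarTrial:
    """Flag channels with poor signal quality.

    Three automated rules stand in for the visual inspection that is usual in
    HDEMG practice: (a) the ratio of flexion-window to baseline-window RMS of
    the band-passed signal must exceed ``snr_min`` ("low_snr" otherwise); (b)
    the fraction of raw-signal power below 20 Hz over the movement window must
    not exceed ``artefact_max`` ("artefact": movement artefact / poor
    electrode contact); (c) bipolar channels touching a dead monopolar
    electrode (movement-window RMS under ``dead_electrode_frac`` of the grid
    median) are flagged "dead_electrode".

    Returns a new trial with ``excluded`` populated.  Raises
    :class:`PipelineError` if every channel is flagged.
    """
    cfg = config or QCConfig()
    fs = trial.sampling_rate
    b0, b1 = seg.baseline
    f0, f1 = seg.flexion
    move_hi = seg.extension[1]

    base_rms = _window_rms(trial.signals, b0, b1)
    act_rms = _window_rms(trial.signals, f0, f1)
    excluded: dict[int, str] = {}
    tiny = 1e-12
    snr = act_rms / np.maximum(base_rms, tiny)
    for i in range(len(trial.channels)):
        if act_rms[i] < tiny or snr[i] < cfg.snr_min:
            excluded[i] = "low_snr"

    if trial.monopolar_signals is not None and trial.electrode_pairs is not None:
        mono_rms = _window_rms(trial.monopolar_signals, f0, move_hi)
        dead = mono_rms < cfg.dead_electrode_frac * np.median(mono_rms)
        for i, (e0, e1) in enumerate(trial.electrode_pairs):
            if i not in excluded and (dead[e0] or dead[e1]):
                excluded[i] = "dead_electrode"

    if trial.raw_signals is not None:
        raw = trial.raw_signals[f0:move_hi]
        nper = min(raw.shape[0], int(2 * fs))
        freqs, psd = sps.welch(raw, fs=fs, nperseg=nper, axis=0)
        total = np.trapezoid(psd, freqs, axis=0)
        lowband = np.trapezoid(psd[freqs < cfg.artefact_hz], freqs[freqs < cfg.artefact_hz], axis=0)
        frac = lowband / np.maximum(total, tiny)
        for i in range(len(trial.channels)):
            if i not in excluded and frac[i] > cfg.artefact_max:
                excluded[i] = "artefact"

    if len(excluded) == len(trial.channels):
        raise PipelineError(
            f"all {len(trial.channels)} channels failed QC for trial {trial.meta.key()}"
        )
    if excluded:
        warnings.warn(
            f"QC flagged {len(excluded)}/{len(trial.channels)} channels "
            f"for trial {trial.meta.key()}",
            stacklevel=2,
        )
    return replace(trial, excluded=excluded)


def envelope(trial: BipolarTrial, cutoff_hz: float = 50.0, order: int = 4) -> EnvelopeTrial:
    """Full-wave rectify and zero-phase low-pass each bipolar channel.

    Excluded channels are processed too (they keep their flags).  Zero-phase
    low-pass filtering of a rectified signal can ring slightly negative; the
    output is clipped at zero so envelopes are non-negative everywhere.
    """
    fs = trial.sampling_rate
    cut = min(cutoff_hz, 0.45 * fs)
    sos = sps.butter(order, cut / (fs / 2), btype="low", output="sos")
    env = sps.sosfiltfilt(sos, np.abs(trial.signals), axis=0)
    np.clip(env, 0.0, None, out=env)
    return EnvelopeTrial(
        envelopes=env,
        source=trial,
        filter_spec={"kind": "butterworth", "order": order, "cutoff_hz": cut, "zero_phase": True},
    )
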