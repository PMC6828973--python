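"""Trunk-angle kinematics: phase segmentation and the flexion-percentage axis.

Each trial's electrogoniometer trace is segmented into four ordered phases --
quiet-standing baseline, trunk flexion, maximal voluntary flexion (MVF, the
sustained full-flexion plateau) and extension -- and trunk angle is mapped to
percent of maximal flexion, the axis on which flexion-relaxation onsets are
expressed.

Flexion start/end are found with a standard kinematic event rule: movement
starts when the smoothed angular velocity first exceeds a fraction of its
peak (default 5%), and the plateau starts when the angle enters and stays
within a tolerance (default 2 deg) of the maximum.  The extension boundary is
the mirror rule on the descending limb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SegmentationError

__all__ = [
    "SegmentationConfig",
    "PhaseSegmentation",
    "segment_phases",
    "angle_to_flexion_pct",
    "time_to_flexion_pct",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables for phase segmentation.

    vel_fraction : movement-onset threshold as a fraction of peak flexion
        velocity (default 0.05).
    angle_tol : plateau tolerance band in degrees below the maximum angle
        (default 2.0).
    baseline_s : length of the quiet-standing baseline window in seconds
        (default 1.0); the window ends ``baseline_gap_s`` (0.5 s) before
        flexion start.
    smooth_hz : low-pass cutoff applied to the angle before differentiation.
    plateau_min_s : minimum dwell inside the tolerance band to accept the
        plateau entry (rejects transient touches).
    """

    vel_fraction: float = 0.05
    angle_tol: float = 2.0
    baseline_s: float = 1.0
    baseline_gap_s: float = 0.5
    smooth_hz: float = 10.0
    plateau_min_s: float = 0.5


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open sample intervals ``[start, end)`` of the four phases."""

    baseline: tuple[int, int]
    flexion: tuple[int, int]
    mvf: tuple[int, int]
    extension: tuple[int, int]
    max_flexion_angle: float
    flexion_duration: float
    sampling_rate: float

    def __post_init__(self) -> None:
        order = [self.baseline, self.flexion, self.mvf, self.extension]
        for (a0, a1), (b0, b1) in zip(order, order[1:]):
            if not (a0 < a1 <= b0 < b1):
                raise SegmentationError(f"phase intervals out of order: {order}")


def _smooth_angle(angle: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return angle.astype(float)
    sos = sps.butter(2, cutoff_hz / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, angle.astype(float))


def segment_phases(
    angle: np.ndarray,
    sampling_rate: float,
    config: SegmentationConfig | None = None,
) -> PhaseSegmentation:
    """Segment a goniometer trace into baseline/flexion/MVF/extension.

    The trace must include a quiet-standing period before movement.  The
    angle is re-referenced to its initial quiet level, so a constant offset
    on the input does not change the result.

    Raises
    ------
    SegmentationError
        If no movement, no plateau, or no return toward neutral is found.
    """
    cfg = config or SegmentationConfig()
    angle = np.asarray(angle, dtype=float)
    fs = float(sampling_rate)
    n = angle.size
    if n < int(2 * fs):
        raise SegmentationError("angle trace shorter than 2 s")

    # re-reference to the initial quiet-standing level
    angle = angle - np.mean(angle[: max(1, int(0.25 * fs))])

    smoothed = _smooth_angle(angle, fs, cfg.smooth_hz)
    vel = np.gradient(smoothed) * fs

    max_angle = float(np.max(smoothed))
    if max_angle < 5.0:
        raise SegmentationError("no flexion movement found (angle never exceeds 5 deg)")

    peak_idx = int(np.argmax(smoothed))
    peak_vel = float(np.max(vel[:peak_idx + 1])) if peak_idx > 0 else 0.0
    if peak_vel <= 0:
        raise SegmentationError("no positive flexion velocity before the angle maximum")
    vthresh = cfg.vel_fraction * peak_vel

    # flexion start: walk back from the rising limb's peak velocity to the
    # last sample at or below the velocity threshold
    pv_idx = int(np.argmax(vel[: peak_idx + 1]))
    below = np.nonzero(vel[: pv_idx + 1] <= vthresh)[0]
    if below.size == 0:
        raise SegmentationError("no quiet period before movement onset")
    flex_start = int(below[-1]) + 1

    # plateau entry: first sample entering the tolerance band that dwells
    # there for at least plateau_min_s
    band = smoothed >= max_angle - cfg.angle_tol
    dwell = max(1, int(cfg.plateau_min_s * fs))
    flex_end = None
    candidates = np.nonzero(band[flex_start:])[0] + flex_start
    c = np.cumsum(band)
    for i in candidates:
        j = min(n, i + dwell)
        if c[j - 1] - (c[i - 1] if i > 0 else 0) == j - i:
            flex_end = int(i)
            break
    if flex_end is None or flex_end <= flex_start:
        raise SegmentationError("no full-flexion plateau found")

    # extension start: mirror rule -- last sample still inside the tolerance
    # band before the descending limb leaves it for good
    after = np.nonzero(band[flex_end:])[0] + flex_end
    ext_start = int(after[-1]) + 1
    if ext_start >= n - 1:
        raise SegmentationError("trace ends inside the full-flexion plateau")
    tail_min = float(np.min(smoothed[ext_start:]))
    if tail_min > 0.5 * max_angle:
        raise SegmentationError("angle never returns toward neutral after the plateau")

    # extension end: velocity magnitude back under threshold near neutral,
    # else end of trace
    low = np.nonzero(
        (np.abs(vel[ext_start:]) <= vthresh) & (smoothed[ext_start:] < 0.25 * max_angle)
    )[0]
    ext_end = int(low[0]) + ext_start if low.size else n
    if ext_end <= ext_start:
        ext_end = n

    base_n = int(cfg.baseline_s * fs)
    gap_n = int(cfg.baseline_gap_s * fs)
    base_end = flex_start - gap_n
    base_start = base_end - base_n
    if base_start < 0:
        raise SegmentationError(
            f"insufficient quiet standing before movement: need "
            f"{cfg.baseline_s + cfg.baseline_gap_s:.2f} s, have {flex_start / fs:.2f} s"
        )

    return PhaseSegmentation(
        baseline=(base_start, base_end),
        flexion=(flex_start, flex_end),
        mvf=(flex_end, ext_start),
        extension=(ext_start, ext_end),
        max_flexion_angle=max_angle,
        flexion_duration=(flex_end - flex_start) / fs,
        sampling_rate=fs,
    )


def angle_to_flexion_pct(angle_value, seg: PhaseSegmentation):
    """Map trunk angle (deg) to percent of maximal flexion, clamped to [0, 100]."""
    if seg.max_flexion_angle <= 0:
        raise ConfigError("max_flexion_angle must be positive")
    pct = 100.0 * np.asarray(angle_value, dtype=float) / seg.max_flexion_angle
    out = np.clip(pct, 0.0, 100.0)
    return float(out) if np.isscalar(angle_value) or out.ndim == 0 else out


def time_to_flexion_pct(sample: int, seg: PhaseSegmentation) -> float:
    """Percent of flexion-phase elapsed time at ``sample``, clamped to [0, 100]."""
    s0, s1 = seg.flexion
    if s1 <= s0:
        raise ConfigError("empty flexion phase")
    return float(np.clip(100.0 * (sample - s0) / (s1 - s0), 0.0, 100.0))
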