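"""Flexion-relaxation onset (EMG offset) detection and topographic mapping.

The FRP onset of one channel is the first sample inside the flexion phase at
which the rectified, low-pass-filtered envelope drops below a baseline-derived
threshold T = mu_b + k * sigma_b (k = 3 by default; mu_b, sigma_b from a
quiet-standing window) and stays below T continuously for a hold period
(default 0.25 s, a debounce against transient dips).  Later re-activation
does not retract a detection.  The onset is expressed as percent of trunk
flexion, either on the angle axis (default) or as percent of flexion-phase
elapsed time.

A subject/side is classified as exhibiting the FRP when the offset is
observed during flexion in more than 50% of the (QC-passed) channels of the
grid; channels without an offset are excluded from the spatial onset map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, PipelineError
from .grid import channel_anatomical_position
from .kinematics import PhaseSegmentation, angle_to_flexion_pct, time_to_flexion_pct
from .preprocess import EnvelopeTrial

__all__ = [
    "DetectionConfig",
    "BaselineStats",
    "ChannelOnset",
    "OnsetMap",
    "baseline_stats",
    "detect_channel_offset",
    "build_onset_map",
    "aggregate_repetitions",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Offset-detector tunables.

    k : baseline SD multiplier in T = mu_b + k * sigma_b.
    hold_s : minimum continuous time below threshold (seconds).
    axis : ``"angle"`` (percent of maximal flexion angle, default) or
        ``"time"`` (percent of flexion-phase elapsed time).
    """

    k: float = 3.0
    hold_s: float = 0.25
    axis: str = "angle"

    def __post_init__(self) -> None:
        if self.axis not in ("angle", "time"):
            raise InputError(f"axis must be 'angle' or 'time', got {self.axis!r}")


@dataclass(frozen=True)
class BaselineStats:
    """Quiet-standing envelope statistics of one channel."""

    mean: float
    sd: float
    window: tuple[int, int]


@dataclass(frozen=True)
class ChannelOnset:
    """Detection result for one bipolar channel."""

    present: bool
    onset_sample: int | None
    onset_pct: float | None
    lattice_position: tuple[int, int]
    never_active: bool = False


@dataclass
class OnsetMap:
    """Per-channel onsets on the bipolar lattice plus subject/side summary."""

    channels: list[ChannelOnset]
    excluded: dict[int, str]
    frp_present: bool
    fraction_channels_with_frp: float
    mean_onset_pct: float | None
    meta: object = None


def baseline_stats(
    env: EnvelopeTrial, seg: PhaseSegmentation, channel: int
) -> BaselineStats:
    """Mean and SD of one channel's envelope over the quiet-standing window."""
    b0, b1 = seg.baseline
    if (b1 - b0) < 0.25 * env.sampling_rate:
        raise InputError("baseline window shorter than 0.25 s; SD would be unstable")
    x = env.envelopes[b0:b1, channel]
    return BaselineStats(mean=float(np.mean(x)), sd=float(np.std(x)), window=(b0, b1))


def _first_hold_crossing(below: np.ndarray, start: int, stop: int, hold_n: int) -> int | None:
    """First i in [start, stop) with ``below[i:i+hold_n]`` all true.

    The hold window may extend past ``stop`` (relaxation continuing into the
    next phase still counts) but not past the trace end.
    """
    n = below.size
    i_max = min(stop, n - hold_n + 1)
    if i_max <= start:
        return None
    c = np.concatenate([[0], np.cumsum(below)])
    idx = np.arange(start, i_max)
    hits = np.nonzero((c[idx + hold_n] - c[idx]) == hold_n)[0]
    return int(idx[hits[0]]) if hits.size else None


def detect_channel_offset(
    env: EnvelopeTrial,
    seg: PhaseSegmentation,
    channel: int,
    config: DetectionConfig | None = None,
) -> ChannelOnset:
    """Detect the FRP onset (EMG offset) of one channel.

    Raises :class:`InputError` if the baseline SD is undefined.  An envelope
    already below threshold for the entire flexion phase is reported present
    with ``onset_pct = 0`` and the ``never_active`` flag set.
    """
    cfg = config or DetectionConfig()
    base = baseline_stats(env, seg, channel)
    if not np.isfinite(base.sd):
        raise InputError(f"baseline SD undefined for channel {channel}")
    thresh = base.mean + cfg.k * base.sd

    f0, f1 = seg.flexion
    x = env.envelopes[:, channel]
    below = x < thresh
    lattice = env.source.channels[channel].lattice_position
    hold_n = max(1, int(round(cfg.hold_s * env.sampling_rate)))

    onset = _first_hold_crossing(below, f0, f1, hold_n)
    if onset is None:
        return ChannelOnset(False, None, None, lattice)
    never_active = bool(below[f0:f1].all())
    if cfg.axis == "angle":
        pct = angle_to_flexion_pct(env.source.angle[onset], seg)
    else:
        pct = time_to_flexion_pct(onset, seg)
    if never_active:
        pct = 0.0
    return ChannelOnset(True, int(onset), float(pct), lattice, never_active=never_active)


def build_onset_map(
    env: EnvelopeTrial,
    seg: PhaseSegmentation,
    config: DetectionConfig | None = None,
) -> OnsetMap:
    """Run offset detection on every QC-passed channel and classify the grid.

    ``frp_present`` follows the strict >50%-of-channels rule; QC-excluded
    channels drop out of the denominator.
    """
    src = env.source
    usable = src.included
    if len(usable) < 0.5 * len(src.channels):
        raise PipelineError(
            f"only {len(usable)}/{len(src.channels)} channels passed QC for "
            f"trial {src.meta.key()}; onset map unreliable"
        )
    results: list[ChannelOnset] = []
    for i in range(len(src.channels)):
        if i in src.excluded:
            results.append(
                ChannelOnset(False, None, None, src.channels[i].lattice_position)
            )
        else:
            results.append(detect_channel_offset(env, seg, i, config))
    n_present = sum(1 for i in usable if results[i].present)
    fraction = n_present / len(usable)
    onsets = [results[i].onset_pct for i in usable if results[i].present]
    return OnsetMap(
        channels=results,
        excluded=dict(src.excluded),
        frp_present=fraction > 0.5,
        fraction_channels_with_frp=fraction,
        mean_onset_pct=float(np.mean(onsets)) if onsets else None,
        meta=src.meta,
    )


def aggregate_repetitions(
    maps: list[OnsetMap], profiles: list[np.ndarray] | None = None
) -> tuple[OnsetMap, np.ndarray | None]:
    """Collapse repetitions into one representative map (and amplitude profile).

    Channel-wise: presence by majority across repetitions (ties count as
    present, with a warning); onset = mean of onset_pct over the repetitions
    where the channel was present.  A channel QC-excluded in some repetitions
    contributes only its usable repetitions; one excluded everywhere stays
    excluded.  Amplitude profiles are averaged element-wise.
    """
    if not maps:
        raise InputError("no repetitions to aggregate")
    n_ch = len(maps[0].channels)
    channels: list[ChannelOnset] = []
    excluded: dict[int, str] = {}
    for i in range(n_ch):
        usable = [m.channels[i] for m in maps if i not in m.excluded]
        if not usable:
            excluded[i] = ";".join(sorted({m.excluded[i] for m in maps if i in m.excluded}))
            channels.append(ChannelOnset(False, None, None, maps[0].channels[i].lattice_position))
            continue
        n_present = sum(ch.present for ch in usable)
        if 2 * n_present == len(usable):
            warnings.warn(
                f"presence tie on channel {i} ({n_present}/{len(usable)}); counting as present",
                stacklevel=2,
            )
        present = 2 * n_present >= len(usable) and n_present > 0
        if present:
            pct = float(np.mean([ch.onset_pct for ch in usable if ch.present]))
        else:
            pct = None
        channels.append(
            ChannelOnset(present, None, pct, maps[0].channels[i].lattice_position)
        )
    usable_idx = [i for i in range(n_ch) if i not in excluded]
    n_present = sum(1 for i in usable_idx if channels[i].present)
    fraction = n_present / len(usable_idx) if usable_idx else 0.0
    onsets = [channels[i].onset_pct for i in usable_idx if channels[i].present]
    agg = OnsetMap(
        channels=channels,
        excluded=excluded,
        frp_present=fraction > 0.5,
        fraction_channels_with_frp=fraction,
        mean_onset_pct=float(np.mean(onsets)) if onsets else None,
        meta=maps[0].meta,
    )
    profile = None
    if profiles:
        lens = {len(p) for p in profiles}
        if len(lens) > 1:
            m = min(lens)
            warnings.warn(f"profiles of unequal length; truncating to {m} epochs", stacklevel=2)
            profiles = [np.asarray(p)[:m] for p in profiles]
        profile = np.mean(np.stack([np.asarray(p, dtype=float) for p in profiles]), axis=0)
    return agg, profile
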