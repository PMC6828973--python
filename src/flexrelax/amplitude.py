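"""Epoch-wise RMS amplitude profiles normalized to the extension-phase peak.

Per repetition, the band-passed bipolar signals are cut into adjacent,
non-overlapping 1 s windows anchored at the detected flexion and MVF phase
starts (nominally 4 flexion + 8 MVF epochs).  The per-channel RMS of each
window is averaged over the QC-passed channels of the grid, and every epoch
value is expressed as a percentage of the peak 1 s grid-mean RMS during the
extension phase -- the window of maximal paraspinal effort, which makes
profiles comparable across subjects and electrode impedances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, PipelineError
from .kinematics import PhaseSegmentation
from .preprocess import BipolarTrial

__all__ = ["EpochAmplitudeProfile", "epoch_rms", "normalize_profile"]

NOMINAL_EPOCHS = (4, 8)  # flexion, MVF


@dataclass
class EpochAmplitudeProfile:
    """Grid-mean RMS per 1 s epoch; ``epochs`` is the normalized (%) curve."""

    raw_grid_rms: np.ndarray
    phase_labels: list[str]
    epochs: np.ndarray | None = None
    normalization_reference: float | None = None
    meta: object = None


def _phase_windows(
    signals: np.ndarray,
    usable: list[int],
    lo: int,
    hi: int,
    fs: float,
    nominal: int | None,
    phase_name: str,
) -> list[float]:
    win = int(round(fs))
    # a phase within 50 ms of containing k whole windows counts as k; the
    # last window may overrun the (fuzzy) detected phase boundary by that much
    avail = int((hi - lo) / win + 0.05)
    n_win = avail if nominal is None else min(nominal, avail)
    while n_win > 0 and lo + n_win * win > signals.shape[0]:
        n_win -= 1
    if nominal is not None and avail < nominal:
        warnings.warn(
            f"{phase_name} phase shorter than nominal: {avail} of {nominal} epochs",
            stacklevel=3,
        )
    values = []
    for w in range(n_win):
        block = signals[lo + w * win : lo + (w + 1) * win][:, usable]
        values.append(float(np.mean(np.sqrt(np.mean(np.square(block), axis=0)))))
    return values


def epoch_rms(trial: BipolarTrial, seg: PhaseSegmentation) -> EpochAmplitudeProfile:
    """Raw grid-mean RMS per epoch (flexion then MVF windows).

    Windows are anchored at the detected phase starts; extra phase duration
    is truncated, short phases yield fewer windows with a warning.
    """
    usable = trial.included
    if not usable:
        raise PipelineError(f"no usable channels for trial {trial.meta.key()}")
    fs = trial.sampling_rate
    if seg.flexion[1] - seg.flexion[0] < fs or seg.mvf[1] - seg.mvf[0] < fs:
        raise InputError("flexion and MVF phases must each last at least 1 s")
    n_flex, n_mvf = NOMINAL_EPOCHS
    flex = _phase_windows(trial.signals, usable, *seg.flexion, fs, n_flex, "flexion")
    mvf = _phase_windows(trial.signals, usable, *seg.mvf, fs, n_mvf, "MVF")
    return EpochAmplitudeProfile(
        raw_grid_rms=np.asarray(flex + mvf),
        phase_labels=["flexion"] * len(flex) + ["mvf"] * len(mvf),
        meta=trial.meta,
    )


def normalize_profile(
    profile: EpochAmplitudeProfile, trial: BipolarTrial, seg: PhaseSegmentation
) -> EpochAmplitudeProfile:
    """Express each epoch as % of the peak extension-phase 1 s grid-mean RMS."""
    fs = trial.sampling_rate
    if seg.extension[1] - seg.extension[0] < fs:
        raise InputError("extension phase shorter than 1 s; no normalization reference")
    ext = _phase_windows(trial.signals, trial.included, *seg.extension, fs, None, "extension")
    reference = max(ext)
    if reference <= 0:
        raise PipelineError(f"degenerate trial {trial.meta.key()}: zero extension-phase RMS")
    profile.normalization_reference = reference
    profile.epochs = 100.0 * profile.raw_grid_rms / reference
    return profile
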