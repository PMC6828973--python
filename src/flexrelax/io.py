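"""On-disk trial format: delimited numeric matrix + structured-text sidecar.

One trial is stored as a CSV with columns ``time_s, angle_deg, emg_000 ...``
(EMG channels in grid enumeration order) next to a ``<name>.meta.yaml``
sidecar carrying sampling rate, grid layout, subject identity and units.
Vendor acquisition containers are out of scope; :func:`read_trial` is the
import hook to adapt.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .errors import InputError
from .grid import GridLayout
from .preprocess import MonopolarTrial, TrialMeta

__all__ = ["write_trial", "read_trial", "iter_trial_files", "trial_filename"]


def trial_filename(meta: TrialMeta) -> str:
    return f"{meta.subject}_{meta.side}_rep{meta.repetition}"


def _layout_to_dict(layout: GridLayout) -> dict:
    return {
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "ied_mm": layout.inter_electrode_distance,
        "missing_corner": list(layout.missing_corner) if layout.missing_corner else None,
        "orientation": layout.orientation,
    }


def _layout_from_dict(d: dict) -> GridLayout:
    return GridLayout(
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        inter_electrode_distance=float(d["ied_mm"]),
        missing_corner=tuple(d["missing_corner"]) if d.get("missing_corner") else None,
        orientation=d.get("orientation", "caudal_row_first"),
    )


def write_trial(directory: str | Path, trial: MonopolarTrial) -> Path:
    """Write one trial (CSV + YAML sidecar); returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = trial_filename(trial.meta)
    csv_path = directory / f"{base}.csv"
    n = trial.n_samples
    t = np.arange(n) / trial.sampling_rate
    block = np.column_stack([t, trial.angle, trial.signals.astype(np.float32)])
    header = "time_s,angle_deg," + ",".join(
        f"emg_{i:03d}" for i in range(trial.signals.shape[1])
    )
    np.savetxt(csv_path, block, delimiter=",", header=header, comments="", fmt="%.6g")
    meta = {
        "sampling_rate": float(trial.sampling_rate),
        "layout": _layout_to_dict(trial.layout),
        "subject": trial.meta.subject,
        "group": trial.meta.group,
        "side": trial.meta.side,
        "repetition": int(trial.meta.repetition),
        "units": {"angle": "deg", "emg": "arbitrary"},
    }
    with open(directory / f"{base}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return csv_path


def read_trial(csv_path: str | Path) -> MonopolarTrial:
    """Read one trial written by :func:`write_trial`."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix("").with_suffix(".meta.yaml")
    if not sidecar.exists():
        sidecar = csv_path.parent / (csv_path.stem + ".meta.yaml")
    if not sidecar.exists():
        raise InputError(f"missing metadata sidecar for {csv_path}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    block = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    if block.ndim != 2 or block.shape[1] < 3:
        raise InputError(f"malformed trial matrix {csv_path}")
    return MonopolarTrial(
        signals=block[:, 2:].astype(np.float32),
        sampling_rate=float(meta["sampling_rate"]),
        angle=block[:, 1],
        layout=_layout_from_dict(meta["layout"]),
        meta=TrialMeta(
            subject=str(meta["subject"]),
            group=str(meta["group"]),
            side=str(meta["side"]),
            repetition=int(meta["repetition"]),
        ),
    )


def iter_trial_files(directory: str | Path) -> Iterator[Path]:
    """Trial CSVs in a directory, deterministically sorted."""
    directory = Path(directory)
    yield from sorted(p for p in directory.glob("*.csv") if not p.name.startswith("truth_"))
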