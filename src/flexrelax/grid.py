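"""Electrode-grid geometry and the monopolar-to-bipolar channel mapping.

A high-density surface EMG grid is a rectangular lattice of electrodes
(default 13 rows x 5 columns, 8 mm inter-electrode distance) with one corner
electrode absent as a directional reference, giving 64 physical electrodes.
Rows run along the cranio-caudal axis (row 0 = caudal edge, roughly L5,
extending cranially to about L2); columns run medio-laterally.

Single differential (bipolar) channels are formed between vertically adjacent
electrodes along each column -- the muscle-fiber direction -- which for the
default layout yields 59 bipolar signals.  Each bipolar channel lives on a
12 x 5 "bipolar lattice" whose node (r, c) is the midpoint of electrodes
(r, c) and (r+1, c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

__all__ = [
    "GridLayout",
    "BipolarChannelIndex",
    "enumerate_bipolar_channels",
    "channel_anatomical_position",
]


@dataclass(frozen=True)
class GridLayout:
    """Geometry of one electrode grid.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (electrode rows x columns).
    inter_electrode_distance
        Centre-to-centre spacing in millimetres.
    missing_corner
        ``(row, col)`` of the absent corner electrode, or ``None`` for a
        complete lattice.  Defaults to the cranial-lateral corner.
    orientation
        ``"caudal_row_first"`` (row 0 is the caudal edge, the default) or
        ``"cranial_row_first"``.
    """

    n_rows: int = 13
    n_cols: int = 5
    inter_electrode_distance: float = 8.0
    missing_corner: tuple[int, int] | None = (12, 4)
    orientation: str = "caudal_row_first"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 1:
            raise ConfigError(f"grid must be at least 2x1, got {self.n_rows}x{self.n_cols}")
        if self.inter_electrode_distance <= 0:
            raise ConfigError("inter_electrode_distance must be positive")
        if self.orientation not in ("caudal_row_first", "cranial_row_first"):
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        if self.missing_corner is not None:
            corners = {
                (0, 0),
                (0, self.n_cols - 1),
                (self.n_rows - 1, 0),
                (self.n_rows - 1, self.n_cols - 1),
            }
            if tuple(self.missing_corner) not in corners:
                raise ConfigError(
                    f"missing_corner {self.missing_corner} is not a corner of a "
                    f"{self.n_rows}x{self.n_cols} grid"
                )

    @property
    def n_electrodes(self) -> int:
        """Number of physical electrodes (64 for the default layout)."""
        return self.n_rows * self.n_cols - (0 if self.missing_corner is None else 1)

    def has_electrode(self, row: int, col: int) -> bool:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            return False
        return self.missing_corner is None or (row, col) != tuple(self.missing_corner)

    def electrode_index(self, row: int, col: int) -> int:
        """Signal-column index of electrode ``(row, col)``.

        Electrodes are ordered column-major: column 0 caudal-to-cranial first,
        then column 1, ...  The missing corner is skipped, so indices are
        contiguous in ``[0, n_electrodes)``.
        """
        if not self.has_electrode(row, col):
            raise ConfigError(f"no electrode at ({row}, {col})")
        idx = col * self.n_rows + row
        if self.missing_corner is not None:
            mr, mc = self.missing_corner
            if mc * self.n_rows + mr < idx:
                idx -= 1
        return idx


@dataclass(frozen=True)
class BipolarChannelIndex:
    """One single-differential channel between two vertically adjacent electrodes.

    ``lattice_position`` is ``(row, col)`` on the (n_rows-1) x n_cols bipolar
    lattice; ``row_pair`` is the ordered (caudal, cranial) electrode row pair.
    ``anatomical_offset`` is the distance in mm of the channel midpoint from
    the caudal grid edge.
    """

    column: int
    row_pair: tuple[int, int]
    lattice_position: tuple[int, int] = field(init=False)
    anatomical_offset: float = 0.0

    def __post_init__(self) -> None:
        r0, r1 = self.row_pair
        if r1 != r0 + 1:
            raise ConfigError(f"row_pair must be adjacent, got {self.row_pair}")
        object.__setattr__(self, "lattice_position", (r0, self.column))


def enumerate_bipolar_channels(layout: GridLayout) -> list[BipolarChannelIndex]:
    """All along-column adjacent electrode pairs that avoid the missing corner.

    Order is deterministic: column-major, caudal to cranial within a column.
    For the default 13x5 layout with one missing corner this yields 59
    channels; a complete R x C lattice yields C*(R-1).
    """
    channels = []
    for col in range(layout.n_cols):
        for row in range(layout.n_rows - 1):
            if layout.has_electrode(row, col) and layout.has_electrode(row + 1, col):
                channels.append(
                    BipolarChannelIndex(
                        column=col,
                        row_pair=(row, row + 1),
                        anatomical_offset=(row + 0.5) * layout.inter_electrode_distance,
                    )
                )
    return channels


def channel_anatomical_position(
    idx: BipolarChannelIndex, layout: GridLayout
) -> tuple[float, float]:
    """Channel midpoint in mm, origin at the caudal-medial grid corner.

    ``x`` runs across columns (medio-lateral), ``y`` along rows
    (caudal-to-cranial).
    """
    ied = layout.inter_electrode_distance
    r0, r1 = idx.row_pair
    return (idx.column * ied, (r0 + r1) / 2.0 * ied)
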