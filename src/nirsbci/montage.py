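"""Optode montage geometry and measurement-channel formation.

A montage is one or two rectangular grids of optodes whose roles (light
emitter vs. detector) alternate in a checkerboard pattern.  Every
horizontally or vertically adjacent emitter-detector pair forms one
measurement channel; the channel signal reflects the cortex between the
pair.  The default montage is two 4x4 grids at 25 mm optode separation,
one over each sensorimotor cortex (left grid centered on C3, right grid
on C4), yielding 48 channels, 24 per hemisphere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

Role = Literal["emitter", "detector"]
Hemisphere = Literal["left", "right"]

#: gap between the two grids, in multiples of the optode spacing
_GRID_GAP_SPACINGS = 3.0


@dataclass(frozen=True)
class OptodeGrid:
    """One rectangular checkerboard of optodes.

    Position (0, 0) is the top-left corner and is always an emitter; roles
    alternate strictly in both grid directions.
    """

    rows: int
    cols: int
    spacing_mm: float
    center_label: str = "C3"
    hemisphere: Hemisphere = "left"
    x_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if self.spacing_mm <= 0:
            raise ValueError(f"optode spacing must be positive, got {self.spacing_mm}")

    def role_at(self, row: int, col: int) -> Role:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"position ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return "emitter" if (row + col) % 2 == 0 else "detector"

    def position_mm(self, row: int, col: int) -> tuple[float, float]:
        """Planar (x, y) of an optode; y grows toward posterior rows."""
        return (self.x_offset_mm + col * self.spacing_mm, row * self.spacing_mm)


class Channel(NamedTuple):
    """One emitter-detector pair; ``index`` is 1-based."""

    index: int
    emitter_mm: tuple[float, float]
    detector_mm: tuple[float, float]
    hemisphere: Hemisphere

    @property
    def midpoint_mm(self) -> tuple[float, float]:
        return (
            (self.emitter_mm[0] + self.detector_mm[0]) / 2.0,
            (self.emitter_mm[1] + self.detector_mm[1]) / 2.0,
        )


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel list over one or two checkerboard grids."""

    grids: tuple[OptodeGrid, ...]
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        indices = [ch.index for ch in self.channels]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("channel indices must be contiguous from 1")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def spacing_mm(self) -> float:
        return self.grids[0].spacing_mm

    def hemisphere_channels(self, hemisphere: Hemisphere) -> list[int]:
        """1-based indices of the channels on one hemisphere."""
        return [ch.index for ch in self.channels if ch.hemisphere == hemisphere]

    def hemisphere_of(self, index: int) -> Hemisphere:
        return self.channels[index - 1].hemisphere

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "channel": ch.index,
                "emitter_x_mm": ch.emitter_mm[0],
                "emitter_y_mm": ch.emitter_mm[1],
                "detector_x_mm": ch.detector_mm[0],
                "detector_y_mm": ch.detector_mm[1],
                "hemisphere": ch.hemisphere,
            }
            for ch in self.channels
        ]
        return pd.DataFrame(rows)

    def write_table(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def layout_hash(self) -> str:
        payload = self.to_table().to_csv(index=False).encode()
        return hashlib.md5(payload).hexdigest()


def checkerboard_channel_count(rows: int, cols: int) -> int:
    """Adjacent emitter-detector pairs in one r x c checkerboard: r(c-1) + c(r-1)."""
    return rows * (cols - 1) + cols * (rows - 1)


def build_checkerboard_layout(
    grid_rows: int = 4,
    grid_cols: int = 4,
    n_grids: int = 2,
    spacing_mm: float = 25.0,
) -> ChannelLayout:
    """Build the channel layout over one or two checkerboard optode grids.

    Channels are all horizontally/vertically adjacent emitter-detector pairs
    within each grid, indexed grid-major (left grid first), then by emitter
    position (row-major), then by detector position.  Grid 1 covers the left
    hemisphere (centered on C3), grid 2 the right hemisphere (C4).

    Parameters
    ----------
    grid_rows, grid_cols
        Grid shape; must be >= 1.
    n_grids
        1 (left hemisphere only) or 2 (bilateral, the default montage).
    spacing_mm
        Emitter-detector separation in millimetres.
    """
    if n_grids not in (1, 2):
        raise ValueError(f"n_grids must be 1 or 2, got {n_grids}")

    grid_width = grid_cols * spacing_mm
    grids = []
    for g in range(n_grids):
        grids.append(
            OptodeGrid(
                rows=grid_rows,
                cols=grid_cols,
                spacing_mm=spacing_mm,
                center_label="C3" if g == 0 else "C4",
                hemisphere="left" if g == 0 else "right",
                x_offset_mm=g * (grid_width + _GRID_GAP_SPACINGS * spacing_mm),
            )
        )

    channels: list[Channel] = []
    index = 1
    for grid in grids:
        for er in range(grid.rows):
            for ec in range(grid.cols):
                if grid.role_at(er, ec) != "emitter":
                    continue
                neighbours = [(er - 1, ec), (er, ec - 1), (er, ec + 1), (er + 1, ec)]
                neighbours = [
                    (r, c)
                    for r, c in neighbours
                    if 0 <= r < grid.rows and 0 <= c < grid.cols
                ]
                # sort detectors by row-major position index
                for dr, dc in sorted(neighbours, key=lambda rc: (rc[0], rc[1])):
                    channels.append(
                        Channel(
                            index=index,
                            emitter_mm=grid.position_mm(er, ec),
                            detector_mm=grid.position_mm(dr, dc),
                            hemisphere=grid.hemisphere,
                        )
                    )
                    index += 1

    return ChannelLayout(grids=tuple(grids), channels=tuple(channels))
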