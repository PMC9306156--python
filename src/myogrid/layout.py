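"""Electrode-grid geometry for a four-grid HD-EMG montage on the forearm.

The default montage is four 8x8 grids with 10 mm inter-electrode distance
(256 monopolar channels).  Grid 1 sits on the ventral side of the distal
forearm; grids 2-4 form a closed ring around the proximal forearm.  The ring
therefore exposes 24 circumferential columns.  Channels are addressed either
by a flat index (0..255) or by (grid, row, col), and carry cylindrical
coordinates (theta, z) used by the signal simulator's spatial model.

Row 1 of each proximal grid is taken as the distal edge; z grows toward the
elbow by one inter-electrode distance per row.  Ring column 1 is anchored at
grid 2, column 1 (the anchor is a documented convention; any fixed anchor
preserves the equidistant spacing of the circumferential selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ChannelRef",
    "GridLayout",
    "ChannelSet",
    "build_layout",
    "build_default_layout",
    "circ_select",
    "substitute_corrupted",
    "all_select",
    "CIRC_ROW",
]

#: Row of the proximal grids used by the circumferential (CIRC) selection,
#: counted from the distal edge.
CIRC_ROW = 4


@dataclass(frozen=True)
class ChannelRef:
    """One electrode pad: flat index, grid address and cylindrical position."""

    index: int
    grid: int
    row: int
    col: int
    theta: float  # radians in [0, 2*pi); circumferential position
    z: float  # mm; grows proximally, 0 at the distal edge of the ring


@dataclass(frozen=True)
class GridLayout:
    """Complete montage: channel table, pitch and corrupted-channel set."""

    channels: tuple[ChannelRef, ...]
    ied_mm: float = 10.0
    corrupted: frozenset[int] = field(default_factory=frozenset)
    n_grids: int = 4
    rows: int = 8
    cols: int = 8

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_ring_columns(self) -> int:
        """Circumferential columns of the proximal ring (grids 2..n_grids)."""
        return (self.n_grids - 1) * self.cols

    @property
    def radius_mm(self) -> float:
        """Forearm radius implied by the closed ring of proximal grids."""
        return self.n_ring_columns * self.ied_mm / (2.0 * math.pi)

    @property
    def clean_channels(self) -> tuple[int, ...]:
        """Flat indices of non-corrupted channels, ascending."""
        return tuple(i for i in range(self.n_channels) if i not in self.corrupted)

    def index_of(self, grid: int, row: int, col: int) -> int:
        if not (1 <= grid <= self.n_grids and 1 <= row <= self.rows and 1 <= col <= self.cols):
            raise ValueError(f"no channel at grid={grid}, row={row}, col={col}")
        return (grid - 1) * self.rows * self.cols + (row - 1) * self.cols + (col - 1)

    def ref(self, index: int) -> ChannelRef:
        if not 0 <= index < self.n_channels:
            raise ValueError(f"channel index {index} outside 0..{self.n_channels - 1}")
        return self.channels[index]

    def ring_column(self, ref: ChannelRef) -> int:
        """1-based circumferential column of a proximal-grid channel."""
        if ref.grid < 2:
            raise ValueError(f"channel {ref.index} is on the distal grid, not on the ring")
        return (ref.grid - 2) * self.cols + ref.col

    def with_corrupted(self, corrupted) -> "GridLayout":
        corrupted = frozenset(int(c) for c in corrupted)
        for c in corrupted:
            if not 0 <= c < self.n_channels:
                raise ValueError(f"corrupted channel index {c} outside 0..{self.n_channels - 1}")
        return replace(self, corrupted=corrupted)

    def to_dict(self) -> dict:
        return {
            "n_grids": self.n_grids,
            "rows": self.rows,
            "cols": self.cols,
            "ied_mm": self.ied_mm,
            "corrupted": sorted(self.corrupted),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return build_layout(
            n_grids=d.get("n_grids", 4),
            rows=d.get("rows", 8),
            cols=d.get("cols", 8),
            ied_mm=d.get("ied_mm", 10.0),
            corrupted=d.get("corrupted", ()),
        )


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel indices plus the selection method that produced them."""

    channels: tuple[int, ...]
    method: str  # "SFS" | "CIRC" | "ALL"

    def __post_init__(self):
        if self.method not in ("SFS", "CIRC", "ALL"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in ChannelSet")

    def __len__(self) -> int:
        return len(self.channels)


def build_layout(n_grids: int = 4, rows: int = 8, cols: int = 8, ied_mm: float = 10.0,
                 corrupted=()) -> GridLayout:
    """Construct the montage geometry.

    Grid 1 is distal-ventral: its columns share the circumferential positions
    of grid 2 and its rows extend distally (negative z).  Grids 2..n_grids
    tile the proximal ring contiguously, theta step = 2*pi / ring columns.
    """
    if n_grids < 2:
        raise ValueError("need at least one distal and one proximal grid")
    n_ring = (n_grids - 1) * cols
    dtheta = 2.0 * math.pi / n_ring
    channels = []
    index = 0
    for grid in range(1, n_grids + 1):
        for row in range(1, rows + 1):
            for col in range(1, cols + 1):
                if grid == 1:
                    theta = (col - 1) * dtheta  # ventral arc, aligned with grid 2
                    z = (row - rows - 1) * ied_mm  # distal extension: -rows*ied .. -ied
                else:
                    ring_col = (grid - 2) * cols + col  # 1-based
                    theta = (ring_col - 1) * dtheta
                    z = (row - 1) * ied_mm
                channels.append(ChannelRef(index, grid, row, col, theta, z))
                index += 1
    layout = GridLayout(tuple(channels), ied_mm=ied_mm, n_grids=n_grids, rows=rows, cols=cols)
    return layout.with_corrupted(corrupted)


def build_default_layout(corrupted=()) -> GridLayout:
    """The canonical 256-channel montage (4 grids of 8x8, 10 mm pitch)."""
    return build_layout(4, 8, 8, 10.0, corrupted)


def substitute_corrupted(layout: GridLayout, channel: ChannelRef) -> ChannelRef:
    """Fallback pad for a circumferential-selection channel: one row toward
    the elbow (row CIRC_ROW+1), same grid and column.

    Pure geometry: the substitute is returned whether or not the input channel
    is actually corrupted.  Raises if the substitute itself is corrupted (only
    one fallback level is defined).
    """
    if channel.grid < 2 or channel.row != CIRC_ROW:
        raise ValueError(
            f"channel {channel.index} (grid {channel.grid}, row {channel.row}) is not "
            f"a row-{CIRC_ROW} proximal-grid channel"
        )
    sub_index = layout.index_of(channel.grid, CIRC_ROW + 1, channel.col)
    if sub_index in layout.corrupted:
        raise ValueError(
            f"substitute channel {sub_index} for corrupted channel {channel.index} "
            "is itself corrupted"
        )
    return layout.ref(sub_index)


def circ_select(layout: GridLayout, n: int = 8) -> ChannelSet:
    """Circumferential evenly-distributed selection (CIRC).

    Picks ``n`` channels from row 4 of the proximal grids at equidistant ring
    columns (default n=8: every 3rd of the 24 ring columns, anchored at grid 2
    column 1).  Corrupted members are replaced by the row-5 channel of the
    same column; if that is corrupted too, an error is raised.
    """
    n_ring = layout.n_ring_columns
    if n > n_ring:
        raise ValueError(f"cannot place {n} channels on {n_ring} ring columns")
    if layout.rows < CIRC_ROW + 1:
        raise ValueError(f"layout rows={layout.rows} too few for row-{CIRC_ROW} selection "
                         "with a one-row fallback")
    # equidistant ring columns; exact when n divides the ring, else nearest
    cols = [round(k * n_ring / n) for k in range(n)]
    if len(set(cols)) != n:
        raise ValueError(f"cannot place {n} distinct equidistant channels on "
                         f"{n_ring} ring columns")
    chosen = []
    for k in range(n):
        ring_col = 1 + cols[k]  # 1-based, anchored at grid 2 column 1
        grid = 2 + (ring_col - 1) // layout.cols
        col = (ring_col - 1) % layout.cols + 1
        idx = layout.index_of(grid, CIRC_ROW, col)
        if idx in layout.corrupted:
            idx = substitute_corrupted(layout, layout.ref(idx)).index
        chosen.append(idx)
    return ChannelSet(tuple(chosen), "CIRC")


def all_select(layout: GridLayout) -> ChannelSet:
    """The full-montage benchmark set (all non-corrupted channels)."""
    return ChannelSet(layout.clean_channels, "ALL")
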