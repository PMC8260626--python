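"""Surface grid geometry, fiducial triangulation and side-information cost.

Writer and reader agree on a rectangular grid of dispense/acquire
positions.  On a physical object the grid is anchored by three fiducial
landmarks (surface features with agreed grid indices); an affine map
fitted through them places every other grid point.  Sharing those three
coordinate pairs plus a which-side flag is the entire prior the reader
needs, and its bit cost is tiny next to the payload.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridGeometry",
    "Fiducial",
    "AffineTransform",
    "fit_affine",
    "grid_positions",
    "side_info_bits",
]


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular acquisition grid: 0-based (row, col), row-major order."""

    rows: int = 32
    cols: int = 48
    pitch_mm: float = 2.3

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols


_LABEL_RE = re.compile(r"^X(\d+)Y(\d+)$")


@dataclass(frozen=True)
class Fiducial:
    """A surface landmark: grid index (0-based col, row) + physical mm position."""

    col: int
    row: int
    x_mm: float
    y_mm: float

    @classmethod
    def from_label(cls, label: str, x_mm: float, y_mm: float) -> "Fiducial":
        """Parse a 1-based ``XnnYnn`` label (e.g. ``X23Y09``)."""
        m = _LABEL_RE.match(label.strip().upper())
        if not m:
            raise ValueError(f"bad fiducial label {label!r}; expected XnnYnn")
        return cls(col=int(m.group(1)) - 1, row=int(m.group(2)) - 1, x_mm=x_mm, y_mm=y_mm)

    @property
    def label(self) -> str:
        return f"X{self.col + 1:02d}Y{self.row + 1:02d}"


@dataclass(frozen=True)
class AffineTransform:
    """Map grid indices (col, row) to physical (x, y) mm: ``p = A @ g + b``."""

    matrix: tuple  # 2x2, row-major nested tuples
    offset: tuple  # length-2

    def apply(self, cols, rows) -> np.ndarray:
        a = np.asarray(self.matrix, dtype=float)
        b = np.asarray(self.offset, dtype=float)
        g = np.stack([np.asarray(cols, float), np.asarray(rows, float)], axis=-1)
        return g @ a.T + b


def fit_affine(fiducials) -> AffineTransform:
    """Exact affine map through three non-collinear fiducials.

    Three correspondences determine the six affine parameters uniquely;
    the fit reproduces the fiducials to machine precision.
    """
    fids = list(fiducials)
    if len(fids) != 3:
        raise ValueError(f"exactly 3 fiducials required, got {len(fids)}")
    g = np.array([[f.col, f.row, 1.0] for f in fids])
    area2 = np.linalg.det(g)
    if abs(area2) < 1e-9:
        raise ValueError("fiducial grid points are collinear")
    p = np.array([[f.x_mm, f.y_mm] for f in fids])
    sol = np.linalg.solve(g, p)  # rows: [a_col, a_row, b] for x and y columns
    a = sol[:2].T
    b = sol[2]
    return AffineTransform(
        matrix=tuple(map(tuple, a.tolist())), offset=tuple(b.tolist())
    )


def grid_positions(transform: AffineTransform, geometry: GridGeometry) -> np.ndarray:
    """Physical (x, y) mm of every grid cell, row-major, shape (rows*cols, 2)."""
    rr, cc = np.meshgrid(
        np.arange(geometry.rows), np.arange(geometry.cols), indexing="ij"
    )
    return transform.apply(cc.ravel(), rr.ravel())


def side_info_bits(
    n_fiducials: int, bits_per_axis: int = 8, side_bit: bool = True
) -> int:
    """Bits of prior information the reader needs for spatial registration.

    Each fiducial costs two ``bits_per_axis`` coordinates; one optional
    flag records which face of the object carries the data.
    """
    if n_fiducials < 0 or bits_per_axis <= 0:
        raise ValueError("counts must be positive")
    return n_fiducials * 2 * bits_per_axis + (1 if side_bit else 0)
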