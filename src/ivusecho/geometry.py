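"""Frame and contour data model, rasterization, and compartment masks.

Coordinate convention used throughout the package: 0-based ``(row, col)``
with row increasing downward. Polygon vertices are ``(row, col)`` pairs
(float or int) and polygons are implicitly closed. Pixel membership is
decided at pixel centers (integer coordinates) with the even-odd rule; the
crossing-number test gives the half-open convention, so an axis-aligned
square with corners (10, 10) and (20, 20) covers exactly the 10x10 block of
centers in ``[10, 20) x [10, 20)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShPolygon


class InvalidContourError(ValueError):
    """Raised for contours with < 3 vertices or self-intersections."""


class DegenerateGeometryWarning(UserWarning):
    """Emitted when contour nesting degenerates (e.g. zero wall area)."""


@dataclass(frozen=True)
class Frame:
    """One grey-scale IVUS cross-section.

    Parameters
    ----------
    pixels
        2-D uint8 array of grey levels in [0, 255]; square.
    pixel_spacing_mm
        Isotropic pixel size in mm (> 0).
    center
        (row, col) of the catheter/transducer center, inside the grid.
    index
        Position of the frame in the pullback.
    z_mm
        Longitudinal position, ``index * frame_spacing_mm``.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    center: tuple[float, float]
    index: int = 0
    z_mm: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("frame must be a square 2-D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("grey levels must be in [0, 255]")
        r, c = self.center
        if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
            raise ValueError("catheter center must lie inside the grid")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ContourSet:
    """Closed lumen / scaffold / vessel polygons for one frame.

    Each polygon is an ``(n, 2)`` array of (row, col) vertices, implicitly
    closed.  The vessel contour traces the external elastic membrane (EEM),
    the scaffold the luminal leading edge of the struts, the lumen the inner
    detectable tissue edge.
    """

    lumen: np.ndarray
    scaffold: np.ndarray
    vessel: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.lumen = np.asarray(self.lumen, dtype=float)
        self.scaffold = np.asarray(self.scaffold, dtype=float)
        self.vessel = np.asarray(self.vessel, dtype=float)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"lumen": self.lumen, "scaffold": self.scaffold, "vessel": self.vessel}


@dataclass
class CompartmentMasks:
    """Boolean wall-compartment masks for one frame.

    ``lumen_scaffold`` = inside scaffold, outside lumen;
    ``scaffold_vessel`` = inside vessel, outside scaffold;
    ``total_wall`` = inside vessel, outside lumen.  Where the scaffold
    locally dips inside the lumen, the clipped pixels belong to neither
    annular compartment but remain part of the total wall.
    """

    lumen_scaffold: np.ndarray
    scaffold_vessel: np.ndarray
    total_wall: np.ndarray
    inside: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def validate_polygon(polygon: np.ndarray) -> np.ndarray:
    """Check a polygon is usable: >= 3 vertices and simple (no self-crossing)."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise InvalidContourError("polygon must be an (n, 2) array of (row, col)")
    if poly.shape[0] < 3:
        raise InvalidContourError(f"polygon needs >= 3 vertices, got {poly.shape[0]}")
    # shapely works in (x, y); validity is orientation-independent
    if not _ShPolygon(poly[:, ::-1]).is_valid:
        raise InvalidContourError("polygon is self-intersecting or degenerate")
    return poly


def points_in_polygon(polygon: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing-number) point-in-polygon test.

    A point on a "low" edge counts as inside and on a "high" edge as
    outside, yielding the half-open pixel-center convention.
    """
    poly = np.asarray(polygon, dtype=float)
    r0, c0 = poly[:, 0], poly[:, 1]
    r1, c1 = np.roll(r0, -1), np.roll(c0, -1)
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    inside = np.zeros(rows.shape, dtype=bool)
    for i in range(len(poly)):
        if r0[i] == r1[i]:
            continue  # horizontal edge never crosses a scanline strictly
        crosses = (r0[i] > rows) != (r1[i] > rows)
        with np.errstate(invalid="ignore"):
            c_int = (c1[i] - c0[i]) * (rows - r0[i]) / (r1[i] - r0[i]) + c0[i]
        inside ^= crosses & (cols < c_int)
    return inside


def rasterize_contour(polygon: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple closed polygon to a boolean mask.

    True exactly for pixels whose centers lie inside the polygon under the
    even-odd rule; deterministic for fixed input.
    """
    poly = validate_polygon(polygon)
    nrow, ncol = grid_shape
    mask = np.zeros((nrow, ncol), dtype=bool)
    # work in a bounding box: polygons typically cover a fraction of the grid
    rmin = max(int(np.floor(poly[:, 0].min())), 0)
    rmax = min(int(np.ceil(poly[:, 0].max())) + 1, nrow)
    cmin = max(int(np.floor(poly[:, 1].min())), 0)
    cmax = min(int(np.ceil(poly[:, 1].max())) + 1, ncol)
    if rmin >= rmax or cmin >= cmax:
        return mask
    rr, cc = np.meshgrid(np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij")
    mask[rmin:rmax, cmin:cmax] = points_in_polygon(poly, rr, cc)
    return mask


def build_compartments(contours: ContourSet, grid_shape: tuple[int, int]) -> CompartmentMasks:
    """Construct the lumen-scaffold, scaffold-vessel and total-wall masks."""
    inside = {name: rasterize_contour(poly, grid_shape) for name, poly in contours.as_dict().items()}
    total_wall = inside["vessel"] & ~inside["lumen"]
    if not total_wall.any():
        warnings.warn(
            "vessel does not enclose any wall outside the lumen; returning empty masks",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        empty = np.zeros(grid_shape, dtype=bool)
        return CompartmentMasks(empty, empty.copy(), empty.copy(), inside)
    lumen_scaffold = inside["scaffold"] & ~inside["lumen"] & total_wall
    scaffold_vessel = inside["vessel"] & ~inside["scaffold"] & total_wall
    return CompartmentMasks(lumen_scaffold, scaffold_vessel, total_wall, inside)


def area_mm2(mask: np.ndarray, pixel_spacing_mm: float) -> float:
    """Physical area of a boolean mask: true-pixel count x spacing^2."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be > 0")
    return float(np.count_nonzero(mask)) * pixel_spacing_mm**2


def circle_polygon(center: tuple[float, float], radius_px: float, n_vertices: int = 96) -> np.ndarray:
    """Regular polygon approximating a circle, in (row, col) coordinates."""
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    rows = center[0] - radius_px * np.sin(ang)
    cols = center[1] + radius_px * np.cos(ang)
    return np.column_stack([rows, cols])


def polar_grids(grid_shape: tuple[int, int], center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel radius (px) and angle (degrees in [0, 360)) about ``center``.

    Angular origin is the positive column axis; angle increases
    counterclockwise when the image is viewed with row 0 at the top (i.e.
    mathematically, with the row axis negated).
    """
    rr, cc = np.meshgrid(np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    radius = np.hypot(dr, dc)
    angle = np.degrees(np.arctan2(-dr, dc)) % 360.0
    return radius, angle
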