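"""Adventitial reference construction.

The grey-level classification is normalized against the adventitia, the
bright layer just outside the external elastic membrane (EEM).  Per frame,
a thin ring 0.01-0.21 mm outside the vessel contour is extracted, an
adaptive Otsu threshold is computed on the ring's histogram, and the ring is
split into 2-degree sectors anchored at the catheter center: a sector is
dropped when more than half of its pixels fall below the adaptive threshold
(shadowed or low-signal adventitia, e.g. under pericardium or a side
branch) or when it intersects a user-supplied guidewire angular mask.  The
surviving sectors' histograms from all frames are pooled and the pooled
median becomes the hypo/hyper split for the whole pullback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import Frame, polar_grids, rasterize_contour, validate_polygon

N_SECTORS = 180
SECTOR_DEG = 2.0


class DegenerateHistogramError(ValueError):
    """Histogram empty or concentrated on a single grey level."""


class NoReferenceError(ValueError):
    """No frame contributed any reference-adventitia pixels."""


class EmptyRingWarning(UserWarning):
    pass


@dataclass
class ReferenceAdventitia:
    """Per-frame adventitial reference: ring mask, sector flags, histogram.

    ``histogram`` counts only ring pixels inside included sectors;
    ``adaptive_threshold`` is the Otsu threshold of the *full* ring used for
    the sector decision.
    """

    ring_mask: np.ndarray
    sector_included: np.ndarray  # (180,) bool
    adaptive_threshold: int
    histogram: np.ndarray  # (256,) int counts
    frame_index: int = 0

    @property
    def n_ring_pixels(self) -> int:
        return int(np.count_nonzero(self.ring_mask))

    @property
    def n_included_sectors(self) -> int:
        return int(np.count_nonzero(self.sector_included))


@dataclass
class GlobalReference:
    """Pooled adventitia histogram and its median grey level."""

    pooled_histogram: np.ndarray
    median_threshold: int


def grey_histogram(values: np.ndarray) -> np.ndarray:
    """256-bin count histogram of 8-bit grey levels."""
    return np.bincount(np.asarray(values, dtype=np.int64).ravel(), minlength=256)[:256]


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold of a 256-bin histogram.

    Returns the smallest t in [1, 255] maximizing the between-class
    variance ``w0*w1*(mu0-mu1)^2`` with class 0 the levels < t and class 1
    the levels >= t.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two grey levels carry counts.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("need counts at >= 2 distinct grey levels")
    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    cum = np.cumsum(hist)
    cum_mean = np.cumsum(hist * levels)
    # candidate thresholds t = 1..255; class 0 has levels 0..t-1
    w0 = cum[:-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean[:-1] / w0
        mu1 = (cum_mean[-1] - cum_mean[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b)) + 1  # argmax returns the first (smallest) maximizer


def build_ring(
    vessel_polygon: np.ndarray,
    pixel_spacing_mm: float,
    grid_shape: tuple[int, int],
    d_min_mm: float = 0.01,
    d_max_mm: float = 0.21,
) -> np.ndarray:
    """Ring of pixels outside the vessel contour within [d_min, d_max] mm.

    Distance is the Euclidean distance to the polygon boundary itself (not a
    circle fit), so irregular vessels get a ring of uniform thickness.
    The ring is clipped at the image borders.
    """
    poly = validate_polygon(vessel_polygon)
    if not (d_max_mm > d_min_mm >= 0):
        if d_max_mm == d_min_mm:
            # degenerate band: at most a one-pixel shell can satisfy it
            pass
        else:
            raise ValueError("need d_max_mm >= d_min_mm >= 0")
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be > 0")
    nrow, ncol = grid_shape
    inside = rasterize_contour(poly, grid_shape)
    pad = d_max_mm / pixel_spacing_mm + 2
    rmin = max(int(poly[:, 0].min() - pad), 0)
    rmax = min(int(poly[:, 0].max() + pad) + 1, nrow)
    cmin = max(int(poly[:, 1].min() - pad), 0)
    cmax = min(int(poly[:, 1].max() + pad) + 1, ncol)
    mask = np.zeros(grid_shape, dtype=bool)
    if rmin >= rmax or cmin >= cmax:
        warnings.warn("reference ring lies entirely off-image", EmptyRingWarning, stacklevel=2)
        return mask
    rr, cc = np.meshgrid(np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij")
    outside = ~inside[rmin:rmax, cmin:cmax]
    boundary = shapely.LinearRing(poly[:, ::-1])  # (x, y) = (col, row)
    pts = shapely.points(cc[outside], rr[outside])
    dist_mm = shapely.distance(pts, boundary) * pixel_spacing_mm
    band = (dist_mm >= d_min_mm) & (dist_mm <= d_max_mm)
    sub = np.zeros(rr.shape, dtype=bool)
    sub[outside] = band
    mask[rmin:rmax, cmin:cmax] = sub
    if not mask.any():
        warnings.warn("reference ring is empty on this grid", EmptyRingWarning, stacklevel=2)
    return mask


def sector_indices(angle_deg: np.ndarray) -> np.ndarray:
    """Map angles (degrees in [0, 360)) to 2-degree sector indices 0..179."""
    return np.minimum((angle_deg / SECTOR_DEG).astype(np.int64), N_SECTORS - 1)


def _guidewire_sectors(intervals) -> np.ndarray:
    """Boolean flags of sectors intersecting any (start, end) degree interval.

    Intervals are half-open ``[start, end)`` and may wrap through 0/360.
    """
    hit = np.zeros(N_SECTORS, dtype=bool)
    if not intervals:
        return hit
    edges = np.arange(N_SECTORS) * SECTOR_DEG  # sector s covers [edges[s], edges[s]+2)
    for start, end in intervals:
        start %= 360.0
        end %= 360.0
        if start == end:
            continue
        if start < end:
            hit |= (edges + SECTOR_DEG > start) & (edges < end)
        else:  # wraps through 0
            hit |= (edges + SECTOR_DEG > start) | (edges < end)
    return hit


def exclude_sectors(
    frame: Frame,
    ring_mask: np.ndarray,
    center: tuple[float, float],
    adaptive_threshold: int,
    guidewire_intervals=None,
) -> np.ndarray:
    """Per-sector inclusion flags for the reference ring.

    Sector ``s`` covers angles ``[2s, 2s+2)`` degrees about the catheter
    center.  A sector is excluded when strictly more than half of its ring
    pixels are strictly below the adaptive threshold, when it has no ring
    pixels, or when it intersects the guidewire angular mask.
    """
    if not ring_mask.any():
        raise ValueError("ring mask is empty")
    _, angle = polar_grids(frame.shape, center)
    sect = sector_indices(angle[ring_mask])
    grey = frame.pixels[ring_mask]
    n_pix = np.bincount(sect, minlength=N_SECTORS)
    n_below = np.bincount(sect, weights=(grey < adaptive_threshold), minlength=N_SECTORS)
    included = (n_pix > 0) & ~(n_below * 2 > n_pix)
    included &= ~_guidewire_sectors(guidewire_intervals)
    return included


def build_reference(
    frame: Frame,
    vessel_polygon: np.ndarray,
    d_min_mm: float = 0.01,
    d_max_mm: float = 0.21,
    guidewire_intervals=None,
    ring: np.ndarray | None = None,
) -> ReferenceAdventitia:
    """Full per-frame reference: ring, adaptive threshold, sectors, histogram.

    A precomputed ``ring`` mask may be passed when consecutive frames share
    the same vessel contour.
    """
    if ring is None:
        ring = build_ring(vessel_polygon, frame.pixel_spacing_mm, frame.shape, d_min_mm, d_max_mm)
    if not ring.any():
        return ReferenceAdventitia(
            ring_mask=ring,
            sector_included=np.zeros(N_SECTORS, dtype=bool),
            adaptive_threshold=0,
            histogram=np.zeros(256, dtype=np.int64),
            frame_index=frame.index,
        )
    full_hist = grey_histogram(frame.pixels[ring])
    try:
        thr = otsu_threshold(full_hist)
    except DegenerateHistogramError:
        thr = 0  # constant ring: keep every sector
    included = exclude_sectors(frame, ring, frame.center, thr, guidewire_intervals)
    _, angle = polar_grids(frame.shape, frame.center)
    pix_sect = sector_indices(angle[ring])
    keep = included[pix_sect]
    hist = grey_histogram(frame.pixels[ring][keep])
    return ReferenceAdventitia(ring, included, thr, hist, frame.index)


def pool_reference(references: list[ReferenceAdventitia]) -> GlobalReference:
    """Pool per-frame reference histograms; median is the hypo/hyper split.

    The median is the lower median of the pooled pixel population: the
    smallest grey level g whose cumulative count reaches ``ceil(N/2)``.
    """
    if not references:
        raise NoReferenceError("no frames supplied")
    pooled = np.zeros(256, dtype=np.int64)
    for ref in references:
        pooled += np.asarray(ref.histogram, dtype=np.int64)
    total = int(pooled.sum())
    if total == 0:
        raise NoReferenceError("all frames have empty reference histograms; pullback unanalyzable")
    half = (total + 1) // 2
    median = int(np.searchsorted(np.cumsum(pooled), half))
    return GlobalReference(pooled, median)
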