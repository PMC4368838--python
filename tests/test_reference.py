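"""Adventitial reference: Otsu, ring geometry, sector screening, pooling."""

import numpy as np
import pytest

import ivusecho as iv
from ivusecho.geometry import polar_grids
from ivusecho.reference import (
    DegenerateHistogramError,
    NoReferenceError,
    ReferenceAdventitia,
    grey_histogram,
    sector_indices,
)


def brute_force_otsu(hist):
    """Exhaustive between-class-variance maximizer, smallest winner."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = hist[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * levels[:t]).sum() / w0
        mu1 = (hist[t:] * levels[t:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def random_histogram(rng, n_levels=16):
    hist = np.zeros(256, dtype=np.int64)
    levels = rng.choice(256, size=n_levels, replace=False)
    hist[levels] = rng.integers(1, 100, size=n_levels)
    return hist


class TestOtsu:
    def test_two_delta_tie_breaks_to_smallest(self):
        hist = np.zeros(256, dtype=int)
        hist[10], hist[200] = 50, 50
        assert iv.otsu_threshold(hist) == 11

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            hist = random_histogram(rng)
            assert iv.otsu_threshold(hist) == brute_force_otsu(hist)

    def test_degenerate_histograms_raise(self):
        single = np.zeros(256, dtype=int)
        single[128] = 500
        with pytest.raises(DegenerateHistogramError):
            iv.otsu_threshold(single)
        with pytest.raises(DegenerateHistogramError):
            iv.otsu_threshold(np.zeros(256, dtype=int))


class TestRing:
    def test_circular_vessel_annulus_pixel_count(self):
        spacing = 0.02
        vessel = iv.circle_polygon((120, 120), 2.0 / spacing)
        ring = iv.build_ring(vessel, spacing, (240, 240))
        expected = np.pi * (2.21**2 - 2.01**2) / spacing**2
        assert ring.sum() == pytest.approx(expected, rel=0.05)
        # ring lies strictly outside the vessel
        inside = iv.rasterize_contour(vessel, (240, 240))
        assert not (ring & inside).any()

    def test_degenerate_band_at_most_one_pixel_shell(self):
        # d_min == d_max keeps only pixels at exactly that distance: a few
        # isolated pixels at most, never a band
        vessel = iv.circle_polygon((32, 32), 10)
        ring = iv.build_ring(vessel, 0.05, (64, 64), d_min_mm=0.2, d_max_mm=0.2)
        assert ring.sum() <= int(2 * np.pi * 15) + 1

    def test_matches_brute_force_distance_to_polygon(self):
        spacing = 0.05
        hexagon = iv.circle_polygon((32, 32), 12, n_vertices=6)
        ring = iv.build_ring(hexagon, spacing, (64, 64), d_min_mm=0.05, d_max_mm=0.4)

        def seg_dist(p, a, b):
            ap, ab = p - a, b - a
            t = np.clip(np.dot(ap, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(ap - t * ab)

        inside = iv.rasterize_contour(hexagon, (64, 64))
        expected = np.zeros((64, 64), dtype=bool)
        for r in range(64):
            for c in range(64):
                if inside[r, c]:
                    continue
                d = min(
                    seg_dist(np.array([r, c], float), hexagon[i], hexagon[(i + 1) % 6])
                    for i in range(6)
                ) * spacing
                if abs(d - 0.05) < 1e-9 or abs(d - 0.4) < 1e-9:
                    expected[r, c] = ring[r, c]  # band edge: float tie, either way
                else:
                    expected[r, c] = 0.05 <= d <= 0.4
        assert np.array_equal(ring, expected)


def _ring_frame(grey_by_angle, spacing=0.05, grid=96, radius_px=30):
    """Synthetic frame with a circular vessel and angle-dependent ring grey."""
    center = (grid / 2, grid / 2)
    vessel = iv.circle_polygon(center, radius_px)
    _, angle = polar_grids((grid, grid), center)
    pixels = grey_by_angle(angle).astype(np.uint8)
    frame = iv.Frame(pixels=pixels, pixel_spacing_mm=spacing, center=center)
    ring = iv.build_ring(vessel, spacing, (grid, grid), d_min_mm=0.01, d_max_mm=0.4)
    return frame, ring, center


class TestSectors:
    def test_uniform_bright_ring_keeps_all_sectors(self):
        frame, ring, center = _ring_frame(lambda a: np.full(a.shape, 200.0))
        flags = iv.exclude_sectors(frame, ring, center, adaptive_threshold=100)
        assert flags.all()

    def test_half_dark_ring_excludes_exactly_the_dark_sectors(self):
        frame, ring, center = _ring_frame(lambda a: np.where(a < 180, 200.0, 20.0))
        thr = iv.otsu_threshold(grey_histogram(frame.pixels[ring]))
        assert 20 < thr <= 200
        flags = iv.exclude_sectors(frame, ring, center, adaptive_threshold=thr)
        # brute-force per-sector tally
        _, angle = polar_grids(frame.shape, center)
        sect = sector_indices(angle[ring])
        grey = frame.pixels[ring]
        for s in range(180):
            px = grey[sect == s]
            expected = len(px) > 0 and not ((px < thr).sum() * 2 > len(px))
            assert flags[s] == expected
        assert flags[:90].all() and not flags[90:].any()

    def test_guidewire_mask_dominates_brightness(self):
        frame, ring, center = _ring_frame(lambda a: np.full(a.shape, 200.0))
        flags = iv.exclude_sectors(frame, ring, center, 100, guidewire_intervals=[(350, 10)])
        excluded = np.flatnonzero(~flags)
        assert set(excluded) == {0, 1, 2, 3, 4, 175, 176, 177, 178, 179}

    def test_exclusion_monotone_under_darkening_and_brightening(self):
        rng = np.random.default_rng(5)
        frame, ring, center = _ring_frame(
            lambda a: rng.integers(0, 255, size=a.shape).astype(float)
        )
        thr = 128
        flags = iv.exclude_sectors(frame, ring, center, thr)
        _, angle = polar_grids(frame.shape, center)
        sect_of_pixel = sector_indices(angle)
        px = frame.pixels.copy()
        px[(sect_of_pixel < 90) & ring] = 0  # darken first half
        px[(sect_of_pixel >= 90) & ring] = 254  # brighten second half
        frame2 = iv.Frame(pixels=px, pixel_spacing_mm=0.05, center=center)
        flags2 = iv.exclude_sectors(frame2, ring, center, thr)
        assert not flags2[:90][flags[:90] == False].any()  # excluded stay excluded
        assert flags2[90:][flags[90:]].all()  # included stay included


def _ref(hist):
    return ReferenceAdventitia(
        ring_mask=np.ones((1, 1), bool),
        sector_included=np.ones(180, bool),
        adaptive_threshold=0,
        histogram=np.asarray(hist, dtype=np.int64),
    )


class TestPooling:
    def test_constant_reference(self):
        hist = np.zeros(256, dtype=int)
        hist[97] = 1234
        assert iv.pool_reference([_ref(hist)]).median_threshold == 97

    def test_two_uniform_frames_lower_median(self):
        a, b = np.zeros(256, int), np.zeros(256, int)
        a[0:10] = 5
        b[10:20] = 5
        # lower median of the 100-pixel pooled population (50th smallest value)
        assert iv.pool_reference([_ref(a), _ref(b)]).median_threshold == 9

    def test_matches_pooled_pixel_list_median(self):
        rng = np.random.default_rng(3)
        refs = [_ref(random_histogram(rng, n_levels=20)) for _ in range(5)]
        pooled = iv.pool_reference(refs)
        values = np.concatenate(
            [np.repeat(np.arange(256), r.histogram) for r in refs]
        )
        values.sort()
        lower_median = values[(len(values) + 1) // 2 - 1]
        assert pooled.median_threshold == lower_median
        assert pooled.pooled_histogram.sum() == len(values)

    def test_adding_frame_at_current_median_is_stable(self):
        rng = np.random.default_rng(9)
        refs = [_ref(random_histogram(rng)) for _ in range(3)]
        med = iv.pool_reference(refs).median_threshold
        extra = np.zeros(256, int)
        extra[med] = 137
        assert iv.pool_reference(refs + [_ref(extra)]).median_threshold == med

    def test_all_empty_raises(self):
        with pytest.raises(NoReferenceError):
            iv.pool_reference([_ref(np.zeros(256, int))])
        with pytest.raises(NoReferenceError):
            iv.pool_reference([])
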