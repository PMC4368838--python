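"""Synthetic IVUS pullback generator with ground truth.

Emulates the scenes the analyzer is built for: a speckled layered vessel
cross-section (blood, neointima, wall tissue) with a bright adventitial
band just outside the vessel contour, hyperechogenic strut blocks between
the scaffold and vessel contours whose brightness decays with the residual
polymer molecular weight, an optional low-intensity wedge over the
adventitia (pericardium / side-branch analogue), and an optional calcified
arc casting a radial acoustic shadow.

Speckle follows the standard multiplicative B-mode model: each pixel is
drawn from a Rayleigh distribution whose mean is the local tissue mean
grey level; ``speckle_strength`` blends between the noiseless mean (0) and
full Rayleigh speckle (1).  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classification import Tissue
from .geometry import ContourSet, Frame, build_compartments, circle_polygon, polar_grids

#: Residual number-average molecular weight (kDa) of a poly-L-lactide
#: scaffold across a nine-timepoint degradation series; used as the default
#: cohort schedule.
DEFAULT_MW_SCHEDULE_KDA = (92.9, 84.2, 76.0, 47.1, 26.2, 7.9, 4.7, 3.9, 0.0)

_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of Rayleigh(scale=1)


class PhantomConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Scene and noise parameters for one synthetic pullback.

    Radii must nest: lumen < scaffold < vessel, with room for the
    adventitial band inside the grid.  All grey levels are mean values in
    [0, 255] before speckle.
    """

    grid_size: int = 160
    pixel_spacing_mm: float = 0.025
    frame_spacing_mm: float = 0.5
    n_frames: int = 6
    # layer geometry (mm)
    lumen_radius_mm: float = 1.05
    scaffold_radius_mm: float = 1.25
    vessel_radius_mm: float = 1.5
    adventitia_thickness_mm: float = 0.3
    # layer mean grey levels
    blood_grey: float = 10.0
    neointima_grey: float = 35.0
    wall_grey: float = 45.0
    adventitia_grey: float = 150.0
    background_grey: float = 25.0
    # scaffold struts
    n_struts: int = 8
    strut_width_deg: float = 16.0
    strut_thickness_mm: float = 0.15
    strut_base_grey: float = 230.0
    strut_phase_deg: float = 0.0
    mw_kda: float | None = None  # None -> render at full baseline brightness
    mw_ref_kda: float = DEFAULT_MW_SCHEDULE_KDA[0]
    # low-intensity wedge over the adventitia
    wedge_span_deg: float = 0.0  # 0 disables
    wedge_center_deg: float = 270.0
    wedge_grey: float = 15.0
    # calcified arc with acoustic shadow
    calc_span_deg: float = 0.0  # 0 disables
    calc_center_deg: float = 90.0
    calc_thickness_mm: float = 0.2
    calc_grey: float = 240.0
    shadow_attenuation: float = 0.05
    # noise
    speckle_strength: float = 1.0
    seed: int = 0
    n_contour_vertices: int = 96

    @classmethod
    def wedge_scenario(cls, seed: int = 0, span_deg: float = 120.0, **kw) -> "PhantomConfig":
        """Dark pericardium-like wedge over the adventitia.

        Speckle is moderated so the wedge/adventitia contrast dominates the
        sector decision; the wedge should remove close to
        ``span_deg / 2`` of the 180 reference sectors.
        """
        return cls(seed=seed, wedge_span_deg=span_deg, speckle_strength=0.3, **kw)

    @classmethod
    def discrimination_scenario(cls, seed: int = 0, with_calc: bool = True, **kw) -> "PhantomConfig":
        """High-contrast scene for shadow discrimination.

        Tissue layers are staggered (neointima 60, wall 110, adventitia
        170, strut/calcium 250) so the three-stage iterated Otsu lands
        between the adventitia and the highly echogenic structures, and
        speckle is mild; bright blocks then resolve cleanly into
        upperechogenic (no shadow) versus calcified + unknown (shadow).
        """
        return cls(
            seed=seed,
            neointima_grey=60.0,
            wall_grey=110.0,
            adventitia_grey=170.0,
            strut_base_grey=250.0,
            calc_grey=250.0,
            n_struts=4,
            strut_phase_deg=180.0,
            calc_span_deg=40.0 if with_calc else 0.0,
            calc_center_deg=45.0,
            speckle_strength=0.2,
            **kw,
        )

    @classmethod
    def noiseless_scenario(cls, seed: int = 0, **kw) -> "PhantomConfig":
        """Speckle-free variant of the discrimination scene for exact checks."""
        cfg = cls.discrimination_scenario(seed=seed, **kw)
        cfg.speckle_strength = 0.0
        return cfg

    def validate(self) -> None:
        if not (0 < self.lumen_radius_mm < self.scaffold_radius_mm < self.vessel_radius_mm):
            raise PhantomConfigError("radii must nest: lumen < scaffold < vessel")
        half_field = self.grid_size / 2 * self.pixel_spacing_mm
        outer = self.vessel_radius_mm + self.adventitia_thickness_mm
        if outer >= half_field:
            raise PhantomConfigError(
                f"vessel + adventitia ({outer:.2f} mm) does not fit in the "
                f"{half_field:.2f} mm half-field"
            )
        for g in (self.blood_grey, self.neointima_grey, self.wall_grey,
                  self.adventitia_grey, self.background_grey, self.strut_base_grey,
                  self.wedge_grey, self.calc_grey):
            if not (0 <= g <= 255):
                raise PhantomConfigError("mean grey levels must be in [0, 255]")
        if not (0 <= self.speckle_strength <= 1):
            raise PhantomConfigError("speckle_strength must be in [0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic pullback."""

    label_maps: list[np.ndarray]
    class_areas_mm2: dict[Tissue, float]  # per frame (frames share geometry)
    mw_kda: float | None


@dataclass
class PhantomPullback:
    frames: list[Frame]
    contours: list[ContourSet]
    truth: PhantomTruth
    config: PhantomConfig


def _angle_in_span(angle: np.ndarray, center_deg: float, span_deg: float) -> np.ndarray:
    """Pixels whose angle lies in the half-open span centered on center_deg."""
    lo = (center_deg - span_deg / 2.0) % 360.0
    delta = (angle - lo) % 360.0
    return delta < span_deg


def strut_grey_for_mw(config: PhantomConfig) -> float:
    """Strut mean brightness under the linear degradation mapping.

    Brightness = baseline x Mw / Mw_ref, clipped to [0, baseline]: a fresh
    scaffold renders at full baseline and a fully degraded one is
    echolucent.
    """
    if config.mw_kda is None:
        return config.strut_base_grey
    f = np.clip(config.mw_kda / config.mw_ref_kda, 0.0, 1.0)
    return float(config.strut_base_grey * f)


def _build_scene(config: PhantomConfig):
    """Noise-free mean image, truth label map, and the contour polygons."""
    n = config.grid_size
    center = (n / 2.0, n / 2.0)
    px = config.pixel_spacing_mm
    radius, angle = polar_grids((n, n), center)

    contours = ContourSet(
        lumen=circle_polygon(center, config.lumen_radius_mm / px, config.n_contour_vertices),
        scaffold=circle_polygon(center, config.scaffold_radius_mm / px, config.n_contour_vertices),
        vessel=circle_polygon(center, config.vessel_radius_mm / px, config.n_contour_vertices),
    )
    masks = build_compartments(contours, (n, n))
    lumen_in = masks.inside["lumen"]
    scaffold_in = masks.inside["scaffold"]
    vessel_in = masks.inside["vessel"]

    mean = np.full((n, n), config.background_grey, dtype=float)
    adv_band = ~vessel_in & (radius * px <= config.vessel_radius_mm + config.adventitia_thickness_mm)
    mean[adv_band] = config.adventitia_grey
    mean[vessel_in] = config.wall_grey
    mean[scaffold_in] = config.neointima_grey
    mean[lumen_in] = config.blood_grey

    truth = np.zeros((n, n), dtype=np.uint8)
    truth[masks.total_wall] = Tissue.HYPO

    # struts: bright blocks between scaffold and vessel contours
    if config.n_struts > 0:
        strut_grey = strut_grey_for_mw(config)
        strut_outer_mm = config.scaffold_radius_mm + config.strut_thickness_mm
        radial = ~scaffold_in & vessel_in & (radius * px <= strut_outer_mm)
        positions = (config.strut_phase_deg + np.arange(config.n_struts) * 360.0 / config.n_struts)
        strut_mask = np.zeros((n, n), dtype=bool)
        for pos in positions:
            strut_mask |= radial & _angle_in_span(angle, pos % 360.0, config.strut_width_deg)
        mean[strut_mask] = strut_grey
        truth[strut_mask] = Tissue.UPPER

    # calcified arc plus its radial shadow
    if config.calc_span_deg > 0:
        calc_outer_mm = config.scaffold_radius_mm + config.calc_thickness_mm
        in_span = _angle_in_span(angle, config.calc_center_deg, config.calc_span_deg)
        calc_mask = in_span & ~scaffold_in & vessel_in & (radius * px <= calc_outer_mm)
        shadow_mask = in_span & (radius * px > calc_outer_mm)
        mean[calc_mask] = config.calc_grey
        mean[shadow_mask] *= config.shadow_attenuation
        truth[calc_mask] = Tissue.CALCIFIED
        truth[shadow_mask & masks.total_wall] = Tissue.UNKNOWN

    # low-intensity wedge overlying the adventitia (pericardium analogue)
    if config.wedge_span_deg > 0:
        wedge = ~vessel_in & _angle_in_span(angle, config.wedge_center_deg, config.wedge_span_deg)
        mean[wedge] = config.wedge_grey

    areas = {
        t: float(np.count_nonzero(truth == int(t))) * px**2
        for t in (Tissue.HYPO, Tissue.HYPER, Tissue.UPPER, Tissue.CALCIFIED, Tissue.UNKNOWN)
    }
    return mean, truth, contours, center


def _speckle(mean: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    if strength == 0:
        noisy = mean
    else:
        scale = mean / _RAYLEIGH_MEAN
        ray = rng.rayleigh(scale=np.where(scale > 0, scale, 1.0))
        ray[mean <= 0] = 0.0
        noisy = (1.0 - strength) * mean + strength * ray
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def generate_pullback(config: PhantomConfig) -> PhantomPullback:
    """Render a full synthetic pullback, byte-identical for a fixed seed."""
    config.validate()
    mean, truth, contours, center = _build_scene(config)
    n = config.grid_size
    px_area = config.pixel_spacing_mm**2
    rng = np.random.default_rng(config.seed)
    frames = []
    contour_sets = []
    label_maps = []
    for i in range(config.n_frames):
        pixels = _speckle(mean, config.speckle_strength, rng)
        frames.append(
            Frame(
                pixels=pixels,
                pixel_spacing_mm=config.pixel_spacing_mm,
                center=center,
                index=i,
                z_mm=i * config.frame_spacing_mm,
            )
        )
        contour_sets.append(replace(contours, frame_index=i))
        label_maps.append(truth)
    areas = {
        t: float(np.count_nonzero(truth == int(t))) * px_area
        for t in (Tissue.HYPO, Tissue.HYPER, Tissue.UPPER, Tissue.CALCIFIED, Tissue.UNKNOWN)
    }
    return PhantomPullback(frames, contour_sets, PhantomTruth(label_maps, areas, config.mw_kda), config)


def generate_degradation_cohort(
    n_scaffolds_per_timepoint: int = 3,
    mw_schedule_kda=DEFAULT_MW_SCHEDULE_KDA,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
):
    """Cohort of pullbacks with strut brightness tied to molecular weight.

    One pullback per scaffold per timepoint; each gets an independent
    sub-seed, a small random rotation of the strut pattern, and a mild
    random scaling of the vessel geometry.  Yields
    ``(scaffold_id, timepoint_index, mw_kda, PhantomConfig)`` tuples — call
    :func:`generate_pullback` on each config to render it.  The schedule
    must be monotone non-increasing (a degradation series).

    Returns the list of tuples and a molecular-weight table ready to join
    with the volumetric summary on ``pullback_id``.
    """
    mw = np.asarray(mw_schedule_kda, dtype=float)
    if np.any(np.diff(mw) > 0):
        raise PhantomConfigError("molecular-weight schedule must be monotone non-increasing")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    entries = []
    rows = []
    for ti, m in enumerate(mw):
        for s in range(n_scaffolds_per_timepoint):
            sid = f"t{ti}_s{s}"
            geom_scale = float(1.0 + 0.03 * rng.standard_normal())
            cfg = replace(
                base,
                mw_kda=float(m),
                mw_ref_kda=float(mw[0]) if mw[0] > 0 else base.mw_ref_kda,
                seed=int(rng.integers(0, 2**31 - 1)),
                strut_phase_deg=float(rng.uniform(0, 360)),
                lumen_radius_mm=base.lumen_radius_mm * geom_scale,
                scaffold_radius_mm=base.scaffold_radius_mm * geom_scale,
                vessel_radius_mm=base.vessel_radius_mm * geom_scale,
            )
            cfg.validate()
            entries.append((sid, ti, float(m), cfg))
            rows.append({"pullback_id": sid, "timepoint": ti, "molecular_weight_kda": float(m)})
    return entries, pd.DataFrame(rows)
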