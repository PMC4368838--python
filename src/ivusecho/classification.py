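"""Per-pixel five-class echogenicity labeling with acoustic-shadow logic.

Within the wall (between lumen and vessel contours) each pixel is labeled
relative to the adventitial reference: below the pooled adventitia median
-> hypoechogenic; at or above the median but not above the high threshold
-> hyperechogenic; above the high threshold -> highly echogenic.  Highly
echogenic pixels are grouped into 8-connected components; a component that
casts an acoustic shadow (an abnormally dark region radially behind it) is
calcified and its shadow, clipped to the wall, is unknown; a component
without shadow is upperechogenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from skimage import measure

from .geometry import CompartmentMasks, Frame, polar_grids
from .thresholding import ThresholdSet


class Tissue(IntEnum):
    OUTSIDE = 0
    HYPO = 1
    HYPER = 2
    UPPER = 3
    CALCIFIED = 4
    UNKNOWN = 5


WALL_CLASSES = (Tissue.HYPO, Tissue.HYPER, Tissue.UPPER, Tissue.CALCIFIED, Tissue.UNKNOWN)

#: Display palette mirroring the usual differential-echogenicity legend
#: (hypo=dark green, hyper=light green, upper=light blue, calcified=white,
#: unknown=grey).
PALETTE = {
    Tissue.OUTSIDE: (0, 0, 0),
    Tissue.HYPO: (0, 100, 0),
    Tissue.HYPER: (144, 238, 144),
    Tissue.UPPER: (173, 216, 230),
    Tissue.CALCIFIED: (255, 255, 255),
    Tissue.UNKNOWN: (128, 128, 128),
}


class ShadowAssessmentWarning(UserWarning):
    """A highly echogenic component had no assessable behind-region."""


@dataclass
class ShadowConfig:
    """Shadow-detector knobs.

    ``depth_mm``: how far radially behind a component the grey level is
    averaged.  ``fraction``: a component casts a shadow when that average is
    below ``fraction * reference_median``.  ``ray_deg``: angular bin width
    of the radial rays.
    """

    depth_mm: float = 0.5
    fraction: float = 0.25
    ray_deg: float = 1.0


@dataclass
class EchoLabelMap:
    """Per-pixel tissue labels for one frame plus the thresholds used."""

    labels: np.ndarray
    thresholds: ThresholdSet
    frame_index: int = 0

    def class_mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)

    def class_counts(self) -> dict[Tissue, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(Tissue))
        return {t: int(counts[int(t)]) for t in Tissue}


def _component_shadow_geometry(
    component_mask: np.ndarray,
    radius: np.ndarray,
    angle: np.ndarray,
    depth_px: float,
    ray_deg: float,
):
    """Per-angular-bin outer radius of the component and its behind-regions.

    Returns (assess_mask, behind_all_mask): pixels within ``depth_px``
    behind the component's outer edge (for the brightness assessment) and
    all pixels behind the edge regardless of depth (for shadow labeling).
    """
    comp_angles = angle[component_mask]
    comp_radii = radius[component_mask]
    bins = (comp_angles / ray_deg).astype(np.int64)
    n_bins = int(np.ceil(360.0 / ray_deg))
    outer = np.full(n_bins, -np.inf)
    np.maximum.at(outer, bins, comp_radii)
    covered = np.isfinite(outer)

    all_bins = (angle / ray_deg).astype(np.int64).clip(max=n_bins - 1)
    in_covered = covered[all_bins]
    outer_here = np.where(in_covered, outer[all_bins.clip(max=n_bins - 1)], np.inf)
    behind_all = in_covered & (radius > outer_here)
    assess = behind_all & (radius <= outer_here + depth_px)
    return assess, behind_all


def detect_shadow(
    frame: Frame,
    component_mask: np.ndarray,
    center: tuple[float, float],
    vessel_mask: np.ndarray,
    reference_median: float,
    config: ShadowConfig | None = None,
) -> bool:
    """Decide whether one highly echogenic component casts an acoustic shadow.

    Radial rays are cast from the catheter center through every angular bin
    the component covers; the grey level of the pixels up to ``depth_mm``
    beyond the component's outer edge is averaged over all rays, and the
    component has a shadow when that mean falls below
    ``fraction * reference_median``.  A component whose behind-region is
    entirely off-image is reported shadowless with a warning.
    """
    config = config or ShadowConfig()
    radius, angle = polar_grids(frame.shape, center)
    depth_px = config.depth_mm / frame.pixel_spacing_mm
    assess, _ = _component_shadow_geometry(component_mask, radius, angle, depth_px, config.ray_deg)
    if not assess.any():
        warnings.warn(
            "highly echogenic component touches the image border; shadow not assessable",
            ShadowAssessmentWarning,
            stacklevel=2,
        )
        return False
    mean_behind = float(frame.pixels[assess].mean())
    return mean_behind < config.fraction * reference_median


def classify_frame(
    frame: Frame,
    masks: CompartmentMasks,
    thresholds: ThresholdSet,
    center: tuple[float, float] | None = None,
    shadow_config: ShadowConfig | None = None,
    median_tie_to_hyper: bool = True,
) -> EchoLabelMap:
    """Label every wall pixel of a frame with one of the five tissue classes.

    The median tie rule (grey exactly equal to the median) defaults to the
    hyperechogenic side so the two classes partition the wall; set
    ``median_tie_to_hyper=False`` to send ties to hypoechogenic instead.
    """
    center = center if center is not None else frame.center
    shadow_config = shadow_config or ShadowConfig()
    grey = frame.pixels.astype(np.int64)
    wall = masks.total_wall
    labels = np.zeros(frame.shape, dtype=np.uint8)

    if median_tie_to_hyper:
        hypo = grey < thresholds.median_threshold
    else:
        hypo = grey <= thresholds.median_threshold
    labels[wall & hypo] = Tissue.HYPO
    labels[wall & ~hypo] = Tissue.HYPER

    high = wall & (grey > thresholds.high_threshold)
    if high.any():
        radius, angle = polar_grids(frame.shape, center)
        depth_px = shadow_config.depth_mm / frame.pixel_spacing_mm
        comp_labels, n_comp = measure.label(high, connectivity=2, return_num=True)
        for comp_id in range(1, n_comp + 1):
            comp = comp_labels == comp_id
            assess, behind_all = _component_shadow_geometry(
                comp, radius, angle, depth_px, shadow_config.ray_deg
            )
            if not assess.any():
                warnings.warn(
                    "highly echogenic component touches the image border; shadow not assessable",
                    ShadowAssessmentWarning,
                    stacklevel=2,
                )
                has_shadow = False
            else:
                mean_behind = float(frame.pixels[assess].mean())
                has_shadow = mean_behind < shadow_config.fraction * thresholds.median_threshold
            if has_shadow:
                labels[comp] = Tissue.CALCIFIED
                # the shadow itself, restricted to the wall and not stealing
                # pixels from other highly echogenic components
                shadow_px = behind_all & wall & ~high
                labels[shadow_px] = Tissue.UNKNOWN
            else:
                labels[comp] = Tissue.UPPER
    return EchoLabelMap(labels, thresholds, frame.index)
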