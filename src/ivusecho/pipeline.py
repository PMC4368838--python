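"""End-to-end pullback analysis: reference -> thresholds -> labels -> volumes."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classification import EchoLabelMap, ShadowConfig, classify_frame
from .geometry import CompartmentMasks, ContourSet, Frame, build_compartments
from .reference import GlobalReference, ReferenceAdventitia, build_reference, pool_reference
from .thresholding import ThresholdSet, make_threshold_set, pullback_high_threshold
from .volumetrics import CompartmentVolumeTable, integrate_volumes


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their standard defaults.

    The adventitial ring spans 0.01-0.21 mm outside the vessel contour and
    is screened in 2-degree sectors; analyzed frames sit 0.5 mm apart; the
    shadow detector looks 0.5 mm behind a bright component and calls a
    shadow below 0.25x the reference median.
    """

    d_min_mm: float = 0.01
    d_max_mm: float = 0.21
    frame_spacing_mm: float = 0.5
    high_scope: str = "per_frame_median"  # or "pooled"
    clamp_high_to_median: bool = True
    median_tie_to_hyper: bool = True
    shadow: ShadowConfig = field(default_factory=ShadowConfig)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PullbackResult:
    thresholds: ThresholdSet
    global_reference: GlobalReference
    references: list[ReferenceAdventitia]
    masks: list[CompartmentMasks]
    label_maps: list[EchoLabelMap]
    volume_table: CompartmentVolumeTable
    config: AnalysisConfig

    def reference_diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "frame_index": r.frame_index,
                    "n_ring_pixels": r.n_ring_pixels,
                    "n_included_sectors": r.n_included_sectors,
                    "adaptive_threshold": r.adaptive_threshold,
                }
                for r in self.references
            ]
        )


def analyze_pullback(
    frames: list[Frame],
    contours: list[ContourSet],
    config: AnalysisConfig | None = None,
    guidewire_intervals=None,
    pullback_id: str = "",
) -> PullbackResult:
    """Run the full differential-echogenicity pipeline on one pullback.

    Per frame: compartment masks from the contours, adventitial ring with
    adaptive Otsu sector screening.  Pullback level: pooled reference
    median (hypo/hyper split) and iterated-Otsu high threshold, then
    five-class labeling of every frame and volumetric integration.
    Frames sharing identical contour geometry reuse their masks and ring.
    """
    if len(frames) != len(contours):
        raise ValueError("one ContourSet is required per frame")
    if not frames:
        raise ValueError("empty pullback")
    config = config or AnalysisConfig()

    from .reference import build_ring

    geom_cache: dict[bytes, tuple] = {}
    masks_list: list[CompartmentMasks] = []
    refs: list[ReferenceAdventitia] = []
    for frame, cs in zip(frames, contours):
        key = cs.lumen.tobytes() + cs.scaffold.tobytes() + cs.vessel.tobytes()
        if key not in geom_cache:
            geom_cache[key] = (
                build_compartments(cs, frame.shape),
                build_ring(cs.vessel, frame.pixel_spacing_mm, frame.shape, config.d_min_mm, config.d_max_mm),
            )
        masks, ring = geom_cache[key]
        masks_list.append(masks)
        refs.append(
            build_reference(
                frame,
                cs.vessel,
                d_min_mm=config.d_min_mm,
                d_max_mm=config.d_max_mm,
                guidewire_intervals=guidewire_intervals,
                ring=ring,
            )
        )

    global_ref = pool_reference(refs)
    high = pullback_high_threshold((f.pixels for f in frames), scope=config.high_scope)
    thresholds = make_threshold_set(
        global_ref.median_threshold, high, scope=config.high_scope, clamp=config.clamp_high_to_median
    )

    label_maps = [
        classify_frame(
            frame,
            masks,
            thresholds,
            shadow_config=config.shadow,
            median_tie_to_hyper=config.median_tie_to_hyper,
        )
        for frame, masks in zip(frames, masks_list)
    ]
    table = integrate_volumes(
        label_maps,
        masks_list,
        pixel_spacing_mm=frames[0].pixel_spacing_mm,
        frame_spacing_mm=config.frame_spacing_mm,
        pullback_id=pullback_id,
    )
    return PullbackResult(thresholds, global_ref, refs, masks_list, label_maps, table, config)


def analyze_cohort(entries, mw_table: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyze a degradation cohort and join volumetrics with molecular weight.

    ``entries`` is the list from
    :func:`ivusecho.phantom.generate_degradation_cohort`.  Pullbacks are
    rendered, analyzed and discarded one at a time; volumes are normalized
    to the cohort mean scaffold length.
    """
    from .phantom import generate_pullback
    from .volumetrics import cohort_summary

    tables = []
    for sid, _ti, _mw, cfg in entries:
        pb = generate_pullback(cfg)
        res = analyze_pullback(pb.frames, pb.contours, config, pullback_id=sid)
        tables.append(res.volume_table)
    summary = cohort_summary(tables, normalize=True)
    return summary.merge(mw_table, on="pullback_id", validate="one_to_one")
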