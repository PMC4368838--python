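"""Compartmental volumetrics of an analyzed pullback.

Analyzed frames sit at a fixed longitudinal interval (0.5 mm by default);
volumes integrate the per-frame class areas by the rectangular rule
(area x spacing), the standard IVUS volumetric convention.  The geometric
volumes (lumen, scaffold, vessel) come from the contour masks and the
neointimal volume is vessel - lumen.  Because pullback lengths differ
between animals, cohort analyses normalize every volume to a common mean
scaffold length, which preserves percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classification import WALL_CLASSES, EchoLabelMap, Tissue
from .geometry import CompartmentMasks, area_mm2

COMPARTMENTS = ("total", "lumen_scaffold", "scaffold_vessel")


class ZeroCompartmentWarning(UserWarning):
    """A compartment had zero volume; its percentages are undefined."""


@dataclass
class CompartmentVolumeTable:
    """Per-class, per-compartment volumes and percentages for one pullback.

    ``volumes_mm3[compartment][class]`` and ``percent[compartment][class]``
    cover the three compartments (total wall, lumen-scaffold,
    scaffold-vessel) and the five tissue classes.  Geometric volumes and
    the scaffold length ride along.  Percentages of an empty compartment
    are NaN.
    """

    volumes_mm3: dict[str, dict[Tissue, float]]
    percent: dict[str, dict[Tissue, float]]
    vessel_mm3: float
    lumen_mm3: float
    scaffold_mm3: float
    scaffold_length_mm: float
    pullback_id: str = ""

    @property
    def neointima_mm3(self) -> float:
        return self.vessel_mm3 - self.lumen_mm3

    def compartment_volume(self, compartment: str) -> float:
        return float(sum(self.volumes_mm3[compartment].values()))

    def as_dataframe(self) -> pd.DataFrame:
        """Tidy long-form table: compartment, tissue_class, volume, percent."""
        rows = [
            {
                "pullback_id": self.pullback_id,
                "compartment": comp,
                "tissue_class": t.name.lower(),
                "volume_mm3": self.volumes_mm3[comp][t],
                "percent": self.percent[comp][t],
            }
            for comp in COMPARTMENTS
            for t in WALL_CLASSES
        ]
        return pd.DataFrame(rows)

    def as_row(self) -> dict[str, float]:
        """One flat summary row (wide format) for cohort CSV output."""
        row: dict[str, float] = {
            "pullback_id": self.pullback_id,
            "scaffold_length_mm": self.scaffold_length_mm,
            "vessel_mm3": self.vessel_mm3,
            "lumen_mm3": self.lumen_mm3,
            "scaffold_mm3": self.scaffold_mm3,
            "neointima_mm3": self.neointima_mm3,
        }
        for comp in COMPARTMENTS:
            for t in WALL_CLASSES:
                name = t.name.lower()
                row[f"{comp}_{name}_mm3"] = self.volumes_mm3[comp][t]
                row[f"{comp}_{name}_pct"] = self.percent[comp][t]
            row[f"{comp}_hyper_upper_mm3"] = (
                self.volumes_mm3[comp][Tissue.HYPER] + self.volumes_mm3[comp][Tissue.UPPER]
            )
        return row


def _class_area(label_map: EchoLabelMap, region: np.ndarray, tissue: Tissue, spacing: float) -> float:
    return area_mm2(label_map.class_mask(tissue) & region, spacing)


def integrate_volumes(
    label_maps: list[EchoLabelMap],
    masks: list[CompartmentMasks],
    pixel_spacing_mm: float,
    frame_spacing_mm: float = 0.5,
    pullback_id: str = "",
) -> CompartmentVolumeTable:
    """Integrate per-frame class areas into a pullback volume table."""
    if len(label_maps) == 0:
        raise ValueError("need at least one analyzed frame")
    if len(label_maps) != len(masks):
        raise ValueError("label maps and compartment masks must pair up per frame")

    vols = {comp: {t: 0.0 for t in WALL_CLASSES} for comp in COMPARTMENTS}
    vessel = lumen = scaffold = 0.0
    for lm, mk in zip(label_maps, masks):
        regions = {
            "total": mk.total_wall,
            "lumen_scaffold": mk.lumen_scaffold,
            "scaffold_vessel": mk.scaffold_vessel,
        }
        for comp, region in regions.items():
            for t in WALL_CLASSES:
                vols[comp][t] += _class_area(lm, region, t, pixel_spacing_mm) * frame_spacing_mm
        vessel += area_mm2(mk.inside["vessel"], pixel_spacing_mm) * frame_spacing_mm
        lumen += area_mm2(mk.inside["lumen"], pixel_spacing_mm) * frame_spacing_mm
        scaffold += area_mm2(mk.inside["scaffold"], pixel_spacing_mm) * frame_spacing_mm

    pct = {comp: {} for comp in COMPARTMENTS}
    for comp in COMPARTMENTS:
        comp_vol = sum(vols[comp].values())
        if comp_vol == 0:
            warnings.warn(
                f"compartment {comp!r} has zero volume; percentages undefined",
                ZeroCompartmentWarning,
                stacklevel=2,
            )
            pct[comp] = {t: float("nan") for t in WALL_CLASSES}
        else:
            pct[comp] = {t: 100.0 * vols[comp][t] / comp_vol for t in WALL_CLASSES}

    return CompartmentVolumeTable(
        volumes_mm3=vols,
        percent=pct,
        vessel_mm3=vessel,
        lumen_mm3=lumen,
        scaffold_mm3=scaffold,
        scaffold_length_mm=len(label_maps) * frame_spacing_mm,
        pullback_id=pullback_id,
    )


def normalize_by_mean_length(
    table: CompartmentVolumeTable, mean_length_mm: float
) -> CompartmentVolumeTable:
    """Rescale all volumes to a common pullback length.

    Normalized volume = raw volume x (mean length / pullback length); this
    weights each pullback equally in cohort summaries and leaves the
    percentages untouched.
    """
    length = table.scaffold_length_mm
    if length <= 0:
        raise ValueError("pullback length must be positive")
    f = mean_length_mm / length
    return replace(
        table,
        volumes_mm3={c: {t: v * f for t, v in d.items()} for c, d in table.volumes_mm3.items()},
        vessel_mm3=table.vessel_mm3 * f,
        lumen_mm3=table.lumen_mm3 * f,
        scaffold_mm3=table.scaffold_mm3 * f,
    )


def cohort_summary(tables: list[CompartmentVolumeTable], normalize: bool = True) -> pd.DataFrame:
    """Wide per-pullback summary; optionally normalized to the cohort mean length."""
    if normalize:
        mean_len = float(np.mean([t.scaffold_length_mm for t in tables]))
        tables = [normalize_by_mean_length(t, mean_len) for t in tables]
    return pd.DataFrame([t.as_row() for t in tables])
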