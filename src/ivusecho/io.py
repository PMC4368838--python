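"""Reading and writing the on-disk pullback dialect.

A pullback dataset is a directory containing ``frames.tif`` (multi-page
8-bit TIFF, one page per analyzed frame) or a ``frames/`` directory of
zero-padded PNGs, a ``contours.csv`` with columns ``frame_index,
contour_type, vertex_order, row, col``, and a ``meta.json`` sidecar with
``pixel_spacing_mm``, ``frame_spacing_mm`` and the catheter ``center``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .classification import PALETTE, EchoLabelMap, Tissue
from .geometry import ContourSet, Frame

CONTOUR_COLUMNS = ["frame_index", "contour_type", "vertex_order", "row", "col"]


def contours_to_dataframe(contour_sets: list[ContourSet]) -> pd.DataFrame:
    rows = []
    for cs in contour_sets:
        for ctype, poly in cs.as_dict().items():
            for order, (r, c) in enumerate(poly):
                rows.append(
                    {
                        "frame_index": cs.frame_index,
                        "contour_type": ctype,
                        "vertex_order": order,
                        "row": r,
                        "col": c,
                    }
                )
    return pd.DataFrame(rows, columns=CONTOUR_COLUMNS)


def dataframe_to_contours(df: pd.DataFrame) -> list[ContourSet]:
    contour_sets = []
    for fi, g in df.groupby("frame_index", sort=True):
        polys = {}
        for ctype, gg in g.groupby("contour_type"):
            gg = gg.sort_values("vertex_order")
            polys[ctype] = gg[["row", "col"]].to_numpy(dtype=float)
        missing = {"lumen", "scaffold", "vessel"} - set(polys)
        if missing:
            raise ValueError(f"frame {fi}: missing contours {sorted(missing)}")
        contour_sets.append(ContourSet(frame_index=int(fi), **polys))
    return contour_sets


def save_pullback(directory, frames: list[Frame], contour_sets: list[ContourSet]) -> Path:
    """Write frames.tif + contours.csv + meta.json into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.pixels for f in frames])
    tifffile.imwrite(d / "frames.tif", stack)
    contours_to_dataframe(contour_sets).to_csv(d / "contours.csv", index=False)
    f0 = frames[0]
    spacing = frames[1].z_mm - frames[0].z_mm if len(frames) > 1 else 0.5
    meta = {
        "pixel_spacing_mm": f0.pixel_spacing_mm,
        "frame_spacing_mm": spacing,
        "center": list(f0.center),
        "n_frames": len(frames),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


def load_pullback(directory) -> tuple[list[Frame], list[ContourSet], dict]:
    """Load a pullback dataset written by :func:`save_pullback` (or compatible)."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    if (d / "frames.tif").exists():
        stack = tifffile.imread(d / "frames.tif")
        if stack.ndim == 2:
            stack = stack[None]
    else:
        pngs = sorted((d / "frames").glob("*.png"))
        if not pngs:
            raise FileNotFoundError(f"no frames.tif or frames/*.png under {d}")
        stack = np.stack([np.asarray(Image.open(p).convert("L")) for p in pngs])
    frames = [
        Frame(
            pixels=stack[i],
            pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
            center=tuple(meta["center"]),
            index=i,
            z_mm=i * float(meta["frame_spacing_mm"]),
        )
        for i in range(stack.shape[0])
    ]
    contour_sets = dataframe_to_contours(pd.read_csv(d / "contours.csv"))
    frame_idx = {f.index for f in frames}
    missing = sorted({cs.frame_index for cs in contour_sets} - frame_idx)
    if missing:
        raise ValueError(f"contours reference absent frames: {missing}")
    return frames, contour_sets, meta


def save_label_png(label_map: EchoLabelMap | np.ndarray, path) -> None:
    """Write a label map as an indexed PNG with the fixed tissue palette."""
    labels = label_map.labels if isinstance(label_map, EchoLabelMap) else label_map
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = []
    for t in Tissue:
        palette.extend(PALETTE[t])
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def load_label_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def labels_run_length(label_map: EchoLabelMap) -> pd.DataFrame:
    """Row-wise run-length encoding: frame_index, row, col_start, length, label."""
    labels = label_map.labels
    rows = []
    for r in range(labels.shape[0]):
        line = labels[r]
        changes = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [len(line)]])
        for s, e in zip(starts, ends):
            if line[s] != Tissue.OUTSIDE:
                rows.append(
                    {
                        "frame_index": label_map.frame_index,
                        "row": r,
                        "col_start": int(s),
                        "length": int(e - s),
                        "label": Tissue(int(line[s])).name.lower(),
                    }
                )
    return pd.DataFrame(rows, columns=["frame_index", "row", "col_start", "length", "label"])
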