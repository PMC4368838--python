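"""High-intensity threshold by three-stage iterated Otsu.

The upper/calcified cut-off is derived by applying Otsu's method to the
full grey-level histogram of a frame, then twice more to the histogram
restricted to levels strictly above the previous threshold.  The per-frame
results are combined across the pullback either as their (lower) median or
by running the iteration once on the pooled histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reference import DegenerateHistogramError, grey_histogram, otsu_threshold


class SaturatedIterationWarning(UserWarning):
    """An Otsu iteration hit a degenerate restricted histogram."""


class ThresholdOrderWarning(UserWarning):
    """high_threshold fell below median_threshold and was clamped."""


@dataclass
class ThresholdSet:
    """Grey-level thresholds driving the five-class labeling.

    ``median_threshold`` splits hypo- from hyperechogenic (pooled
    adventitia median); ``high_threshold`` marks highly echogenic pixels
    (upper/calcified candidates).  ``scope`` records how per-frame high
    thresholds were combined: ``per_frame_median`` or ``pooled``.
    """

    median_threshold: int
    high_threshold: int
    scope: str = "per_frame_median"

    def __post_init__(self):
        for t in (self.median_threshold, self.high_threshold):
            if not (0 <= t <= 255):
                raise ValueError("thresholds must be grey levels in [0, 255]")


def iterated_otsu_high(histogram: np.ndarray, n_iterations: int = 3) -> int:
    """Three-stage iterated Otsu threshold of a full-image histogram.

    Stage 1 thresholds the full histogram; each later stage thresholds only
    the grey levels strictly above the previous threshold.  If a stage hits
    a degenerate restricted histogram (empty or single-valued) the last
    valid threshold is returned with a :class:`SaturatedIterationWarning`.
    """
    hist = np.asarray(histogram, dtype=np.int64).copy()
    t = otsu_threshold(hist)  # stage 1: degenerate input raises here
    for _ in range(n_iterations - 1):
        restricted = hist.copy()
        restricted[: t + 1] = 0  # keep levels strictly above t
        try:
            t = otsu_threshold(restricted)
        except DegenerateHistogramError:
            warnings.warn(
                f"iterated Otsu saturated at threshold {t}; returning last valid stage",
                SaturatedIterationWarning,
                stacklevel=2,
            )
            return t
    return t


def pullback_high_threshold(frames_pixels, scope: str = "per_frame_median") -> int:
    """Combine the per-frame iterated-Otsu thresholds across a pullback.

    ``per_frame_median``: lower median of the per-frame stage-3 thresholds
    (robust to single outlier frames).  ``pooled``: one iterated Otsu on
    the summed histogram of all frames.
    """
    if scope == "pooled":
        pooled = np.zeros(256, dtype=np.int64)
        for px in frames_pixels:
            pooled += grey_histogram(px)
        return iterated_otsu_high(pooled)
    if scope != "per_frame_median":
        raise ValueError(f"unknown high-threshold scope: {scope!r}")
    per_frame = [iterated_otsu_high(grey_histogram(px)) for px in frames_pixels]
    if not per_frame:
        raise ValueError("no frames supplied")
    return int(np.sort(per_frame)[(len(per_frame) - 1) // 2])


def make_threshold_set(
    median_threshold: int,
    high_threshold: int,
    scope: str = "per_frame_median",
    clamp: bool = True,
) -> ThresholdSet:
    """Assemble a :class:`ThresholdSet`, clamping high >= median by default."""
    if high_threshold < median_threshold:
        if clamp:
            warnings.warn(
                f"high threshold {high_threshold} < median {median_threshold}; "
                "clamping to the median",
                ThresholdOrderWarning,
                stacklevel=2,
            )
            high_threshold = median_threshold
        else:
            warnings.warn(
                f"high threshold {high_threshold} < median {median_threshold}",
                ThresholdOrderWarning,
                stacklevel=2,
            )
    return ThresholdSet(median_threshold, high_threshold, scope)
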