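"""Healthy-cohort threshold calibration and color map rendering.

The pathological-slope threshold is read off the mean cumulative histogram
of a healthy cohort: per-subject empirical CDFs of valid slope values are
evaluated on a common grid and averaged with equal subject weight, and the
threshold is the grid value where the mean CDF first reaches the chosen
percentile (default 99.5%). Rendering paints sub-threshold pixels blue and
supra-threshold pixels on a yellow-to-red ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from famap.io_model import SlopeMap, ValidationError

DEFAULT_PERCENTILE = 0.995
DEFAULT_GRID_SIZE = 2048

#: Wraparound margin (px) excluded from calibration and scoring.
DEFAULT_BORDER_MARGIN = 8

_BLUE = np.array([0, 0, 255], dtype=np.uint8)
_BLACK = np.array([0, 0, 0], dtype=np.uint8)


@dataclass
class CumulativeHistogram:
    """Mean empirical CDF of slope values over a subject cohort."""

    grid: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.cdf = np.asarray(self.cdf, dtype=np.float64)
        if np.any(np.diff(self.cdf) < -1e-12):
            raise ValidationError("mean CDF must be non-decreasing")


@dataclass
class PermeabilityThreshold:
    """Slope threshold separating normal from pathological permeability."""

    slope_threshold: float
    percentile: float
    n_subjects: int
    grid_size: int = DEFAULT_GRID_SIZE

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 1:
            raise ValidationError("percentile must lie in (0, 1)")
        if not np.isfinite(self.slope_threshold):
            raise ValidationError("threshold must be finite")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "PermeabilityThreshold":
        with open(path) as fh:
            return cls(**json.load(fh))


def border_margin_mask(
    dims: tuple[int, int], margin: int = DEFAULT_BORDER_MARGIN
) -> np.ndarray:
    """Exclusion mask that is True on a frame border of the given width."""
    mask = np.zeros(dims, dtype=bool)
    if margin > 0:
        mask[:margin, :] = True
        mask[-margin:, :] = True
        mask[:, :margin] = True
        mask[:, -margin:] = True
    return mask


def mean_cumulative_histogram(
    slope_maps: Sequence[SlopeMap],
    exclusion_masks: Sequence[np.ndarray] | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> CumulativeHistogram:
    """Average per-subject empirical slope CDFs on a common grid.

    The grid spans the pooled min..max of valid slopes; averaging subject
    CDFs (rather than pooling pixels) gives each subject equal weight
    regardless of pixel count.
    """
    if not slope_maps:
        raise ValidationError("need at least one slope map")
    if exclusion_masks is None:
        exclusion_masks = [None] * len(slope_maps)
    if len(exclusion_masks) != len(slope_maps):
        raise ValidationError("one exclusion mask per slope map required")

    per_subject = []
    for sm, excl in zip(slope_maps, exclusion_masks):
        values = np.sort(sm.valid_values(excl))
        if values.size:
            per_subject.append(values)
    if not per_subject:
        raise ValidationError("no valid pixels in any slope map")

    lo = min(v[0] for v in per_subject)
    hi = max(v[-1] for v in per_subject)
    grid = np.linspace(lo, hi, grid_size)
    cdf = np.zeros(grid_size)
    for values in per_subject:
        cdf += np.searchsorted(values, grid, side="right") / values.size
    cdf /= len(per_subject)
    return CumulativeHistogram(grid=grid, cdf=cdf)


def derive_threshold(
    cum_hist: CumulativeHistogram, percentile: float = DEFAULT_PERCENTILE
) -> PermeabilityThreshold:
    """Smallest grid value whose mean CDF reaches the percentile."""
    if not 0 < percentile < 1:
        raise ValidationError("percentile must lie in (0, 1)")
    idx = int(np.searchsorted(cum_hist.cdf, percentile, side="left"))
    idx = min(idx, cum_hist.grid.size - 1)
    return PermeabilityThreshold(
        slope_threshold=float(cum_hist.grid[idx]),
        percentile=percentile,
        n_subjects=0,
        grid_size=int(cum_hist.grid.size),
    )


def calibrate_cohort(
    slope_maps: Sequence[SlopeMap],
    exclusion_masks: Sequence[np.ndarray] | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> PermeabilityThreshold:
    """Convenience wrapper: mean cumulative histogram then threshold."""
    hist = mean_cumulative_histogram(slope_maps, exclusion_masks, grid_size)
    thr = derive_threshold(hist, percentile)
    thr.n_subjects = len(slope_maps)
    return thr


def abnormal_fraction(
    slope_map: SlopeMap,
    threshold: PermeabilityThreshold,
    exclusion_mask: np.ndarray | None = None,
) -> float:
    """Fraction of valid, non-excluded pixels with slope above threshold."""
    values = slope_map.valid_values(exclusion_mask)
    if values.size == 0:
        raise ValidationError("no valid pixels to score")
    return float((values > threshold.slope_threshold).mean())


def render_map(
    slope_map: SlopeMap,
    threshold: PermeabilityThreshold,
    ramp_percentile: float = 99.9,
) -> np.ndarray:
    """Render a slope map as an 8-bit RGB image.

    Sub-threshold pixels are uniform blue; supra-threshold pixels ramp
    linearly from yellow (at the threshold) to red (at the given percentile
    of supra-threshold slopes, clipped above); invalid pixels are black.
    Re-rendering the same inputs is bit-identical.
    """
    thr = threshold.slope_threshold
    rgb = np.zeros((*slope_map.slope.shape, 3), dtype=np.uint8)
    rgb[slope_map.valid] = _BLUE
    rgb[~slope_map.valid] = _BLACK

    supra = slope_map.valid & (slope_map.slope > thr)
    if supra.any():
        supra_vals = slope_map.slope[supra]
        red_end = float(np.percentile(supra_vals, ramp_percentile))
        span = red_end - thr
        if span <= 0:
            frac = np.ones_like(supra_vals)
        else:
            frac = np.clip((supra_vals - thr) / span, 0.0, 1.0)
        colors = np.zeros((supra_vals.size, 3), dtype=np.uint8)
        colors[:, 0] = 255
        colors[:, 1] = np.round(255 * (1.0 - frac)).astype(np.uint8)
        rgb[supra] = colors
    return rgb
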