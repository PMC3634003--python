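"""Arterial input function, normalization and per-pixel slope fitting.

Each pixel's intensity time course is divided by the mean intensity of the
major arteries at the same time point, removing dose, illumination and
camera-gain differences. A straight line fitted to the late-phase
normalized course gives the per-pixel slope: washout drives healthy tissue
to non-positive slopes, barrier leakage accumulates dye and drives slopes
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from famap.io_model import FASequence, ROIMask, SlopeMap, ValidationError

#: AIF values below this fraction of the curve maximum mark pre-dye frames.
DEFAULT_FLOOR_FRACTION = 0.10

#: Seconds from injection where the late-phase fit begins.
DEFAULT_FIT_START_S = 120.0

DEFAULT_MIN_POINTS = 4


@dataclass
class AIFCurve:
    """Mean arterial intensity per usable time point (camera units)."""

    t: np.ndarray
    value: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.t.shape != self.value.shape:
            raise ValidationError("AIF times and values must share length")
        if not np.all(np.isfinite(self.value)):
            raise ValidationError("AIF values must be finite")


@dataclass
class NormalizedSequence:
    """Per-pixel AIF-normalized intensities over the retained time points."""

    stack: np.ndarray  # (n_times, rows, cols)
    t: np.ndarray
    saturated: np.ndarray | None = None  # pixels clipped at sensor max

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if self.stack.shape[0] != self.t.shape[0]:
            raise ValidationError("stack depth must match number of times")


def compute_aif(
    registered_sequence: FASequence,
    artery_roi: ROIMask,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> AIFCurve:
    """Mean intensity inside the artery ROI for every usable frame."""
    if not artery_roi.mask.any():
        raise ValidationError("artery ROI is empty")
    if artery_roi.mask.shape != registered_sequence.pixel_dims:
        raise ValidationError("artery ROI dims do not match sequence")
    usable = registered_sequence.usable_indices()
    t = np.array([registered_sequence.frames[i].t for i in usable])
    value = np.array(
        [
            float(registered_sequence.frames[i].pixels[artery_roi.mask].mean())
            for i in usable
        ]
    )
    return AIFCurve(t=t, value=value, floor=floor_fraction * float(value.max()))


def normalize_sequence(
    registered_sequence: FASequence,
    aif: AIFCurve,
    sensor_max: float | None = None,
) -> NormalizedSequence:
    """Divide each usable frame by its AIF value, dropping pre-dye frames.

    Frames whose AIF value is below the curve's floor (division would be
    unstable before dye arrival) are dropped. If ``sensor_max`` is given, a
    per-pixel fraction-clipped mask is recorded so saturated pixels can be
    invalidated during fitting.
    """
    usable = registered_sequence.usable_indices()
    if len(usable) != len(aif.t):
        raise ValidationError("AIF was not computed on this sequence")
    keep = aif.value >= aif.floor
    if not keep.any():
        raise ValidationError("no dye signal: every frame is below the AIF floor")

    frames = [registered_sequence.frames[i] for i, k in zip(usable, keep) if k]
    values = aif.value[keep]
    stack = np.stack([f.pixels / v for f, v in zip(frames, values)])
    t = np.array([f.t for f in frames])

    saturated = None
    if sensor_max is not None:
        raw = np.stack([f.pixels for f in frames])
        saturated = raw >= sensor_max
    return NormalizedSequence(stack=stack, t=t, saturated=saturated)


def fit_slope_map(
    normalized_sequence: NormalizedSequence,
    fit_start_s: float = DEFAULT_FIT_START_S,
    min_points: int = DEFAULT_MIN_POINTS,
) -> SlopeMap:
    """Ordinary-least-squares slope of normalized intensity vs time (s).

    Only time points at or after ``fit_start_s`` enter the fit. Pixels with
    fewer than ``min_points`` finite samples — or clipped at the sensor
    maximum in at least half of the fitted frames — are marked invalid.
    """
    sel = normalized_sequence.t >= fit_start_s
    if sel.sum() < min_points:
        raise ValidationError(
            f"only {int(sel.sum())} time points at t >= {fit_start_s}s; "
            f"need {min_points}"
        )
    t = normalized_sequence.t[sel]
    y = normalized_sequence.stack[sel]

    finite = np.isfinite(y)
    n = finite.sum(axis=0)
    valid = n >= min_points

    y_safe = np.where(finite, y, 0.0)
    t_grid = t[:, None, None] * finite  # per-pixel time support
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = t_grid.sum(axis=0) / n
        y_mean = y_safe.sum(axis=0) / n
        dt = (t[:, None, None] - t_mean) * finite
        dy = (y_safe - y_mean) * finite
        denom = (dt**2).sum(axis=0)
        slope = (dt * dy).sum(axis=0) / denom
    valid &= np.isfinite(slope) & (denom > 0)

    if normalized_sequence.saturated is not None:
        clipped = normalized_sequence.saturated[sel].mean(axis=0)
        valid &= clipped < 0.5

    slope = np.where(valid, slope, 0.0)
    return SlopeMap(slope=slope, valid=valid, n_points=int(sel.sum()))
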