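"""Domain types and file I/O shared by every pipeline stage.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
* frame times are seconds since dye injection;
* intensities are arbitrary camera units (normalization removes the scale);
* invalid slope pixels serialize as NaN so "not fitted" never aliases 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_perimeter

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")

ROI_ROLES = ("artery", "optic_disc", "other")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """A single angiographic frame.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (camera units).
    t
        Acquisition time in seconds since injection.
    quality
        ``"ok"`` or ``"excluded"``.
    eye
        ``"left"``, ``"right"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    t: float
    quality: str = "ok"
    eye: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("frame pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("frame pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("frame pixels must be non-negative")
        if self.t < 0:
            raise ValidationError("frame time must be >= 0 seconds")
        if self.quality not in ("ok", "excluded"):
            raise ValidationError(f"unknown quality flag {self.quality!r}")

    @property
    def usable(self) -> bool:
        return self.quality == "ok"


@dataclass
class FASequence:
    """Time-ordered stack of same-sized frames."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("sequence must contain at least one frame")
        dims = self.frames[0].pixels.shape
        for f in self.frames:
            if f.pixels.shape != dims:
                raise ValidationError(
                    f"mismatched frame size {f.pixels.shape} != {dims}"
                )
        times = np.array([f.t for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_dims(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    def usable_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.frames) if f.usable]

    def as_stack(self, usable_only: bool = False) -> np.ndarray:
        idx = self.usable_indices() if usable_only else range(len(self.frames))
        return np.stack([self.frames[i].pixels for i in idx])


@dataclass
class ROIMask:
    """Binary pixel mask tagged with an anatomical role."""

    mask: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")
        if self.role not in ROI_ROLES:
            raise ValidationError(
                f"ROI role must be one of {ROI_ROLES}, got {self.role!r}"
            )

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ShiftVector:
    """Sub-pixel (row, col) translation between two frames."""

    d_row: float
    d_col: float
    peak_corr: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_row) and np.isfinite(self.d_col)):
            raise ValidationError("shift components must be finite")

    def as_tuple(self) -> tuple[float, float]:
        return (self.d_row, self.d_col)


@dataclass
class SlopeMap:
    """Per-pixel slope of normalized intensity versus time.

    ``slope`` holds normalized-intensity change per second; ``valid`` marks
    pixels where a fit with at least the minimum number of points succeeded.
    """

    slope: np.ndarray
    valid: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.slope = np.asarray(self.slope, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.slope.shape != self.valid.shape:
            raise ValidationError("slope and validity grids must share dims")
        if not np.all(np.isfinite(self.slope[self.valid])):
            raise ValidationError("slope must be finite wherever valid")

    def valid_values(self, exclusion: np.ndarray | None = None) -> np.ndarray:
        keep = self.valid.copy()
        if exclusion is not None:
            keep &= ~np.asarray(exclusion, dtype=bool)
        return self.slope[keep]


@dataclass
class RaterGrid:
    """One rater's 3x3 grid calls plus an overall diagnosis for one eye."""

    squares: np.ndarray
    overall: int
    rater_id: str
    eye_id: str

    def __post_init__(self) -> None:
        self.squares = np.asarray(self.squares, dtype=int)
        if self.squares.size != 9:
            raise ValidationError("grid must have exactly 9 squares")
        self.squares = self.squares.reshape(3, 3)
        if not np.isin(self.squares, (0, 1)).all():
            raise ValidationError("grid squares must be 0 or 1")
        if self.overall not in (0, 1):
            raise ValidationError("overall diagnosis must be 0 or 1")


# ---------------------------------------------------------------------------
# sequence reading
# ---------------------------------------------------------------------------


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to a single channel by unweighted channel mean."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {img.ndim}")
    return img


def read_sequence(directory: str | Path, metadata_path: str | Path) -> FASequence:
    """Read a directory of frame images plus a JSON time sidecar.

    The sidecar maps each image filename to its acquisition time in seconds
    since injection. Frames are returned sorted by time; RGB inputs are
    converted to grayscale by averaging channels.
    """
    directory = Path(directory)
    with open(metadata_path) as fh:
        meta = json.load(fh)
    if not isinstance(meta, dict):
        raise ValidationError("metadata must be a JSON object {filename: seconds}")

    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not files:
        raise ValidationError(f"no image files found in {directory}")

    entries: list[tuple[float, Path]] = []
    for p in files:
        if p.name not in meta:
            raise ValidationError(f"metadata has no time entry for file {p.name!r}")
        entries.append((float(meta[p.name]), p))

    times = [t for t, _ in entries]
    if len(set(times)) != len(times):
        dupes = sorted({t for t in times if times.count(t) > 1})
        raise ValidationError(f"duplicate acquisition timestamps: {dupes}")

    entries.sort(key=lambda e: e[0])
    frames = [Frame(_to_grayscale(iio.imread(p)), t=t) for t, p in entries]
    return FASequence(frames)


def write_sequence(
    sequence: FASequence, directory: str | Path, metadata_name: str = "meta.json"
) -> Path:
    """Write frames as 32-bit float TIFFs plus the JSON time sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict[str, float] = {}
    for i, frame in enumerate(sequence.frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(directory / name, frame.pixels.astype(np.float32))
        meta[name] = float(frame.t)
    meta_path = directory / metadata_name
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return meta_path


# ---------------------------------------------------------------------------
# ROI reading / writing
# ---------------------------------------------------------------------------


def _rasterize_polygon(
    vertices: Sequence[Sequence[float]], dims: tuple[int, int]
) -> np.ndarray:
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValidationError("polygon must be a list of (row, col) vertices")
    mask = np.zeros(dims, dtype=bool)
    rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=dims)
    mask[rr, cc] = True
    if len(verts) >= 2:
        # polygon() can drop edge pixels; the contract includes the boundary
        rr, cc = _draw_perimeter(
            np.round(verts[:, 0]).astype(int),
            np.round(verts[:, 1]).astype(int),
            shape=dims,
            clip=True,
        )
        mask[rr, cc] = True
    else:
        r, c = np.round(verts[0]).astype(int)
        if 0 <= r < dims[0] and 0 <= c < dims[1]:
            mask[r, c] = True
    return mask


def _rle_decode(rle: dict, dims: tuple[int, int]) -> np.ndarray:
    shape = tuple(rle["shape"])
    if shape != tuple(dims):
        raise ValidationError(f"RLE shape {shape} does not match expected {dims}")
    counts = np.asarray(rle["counts"], dtype=np.int64)
    if counts.sum() != dims[0] * dims[1]:
        raise ValidationError("RLE counts do not cover the full frame")
    flat = np.zeros(dims[0] * dims[1], dtype=bool)
    pos, val = 0, False  # runs alternate starting with zeros
    for n in counts:
        if val:
            flat[pos : pos + n] = True
        pos += int(n)
        val = not val
    return flat.reshape(dims)


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        counts = [0] + counts  # runs must start with a zero-run
    return {"shape": list(mask.shape), "counts": counts}


def read_roi(path: str | Path, expected_dims: tuple[int, int]) -> ROIMask:
    """Read a region-of-interest JSON (polygon or run-length mask)."""
    with open(path) as fh:
        data = json.load(fh)
    role = data.get("role")
    if role not in ROI_ROLES:
        raise ValidationError(
            f"ROI role must be one of {ROI_ROLES}, got {role!r} in {path}"
        )
    if "polygon" in data:
        mask = _rasterize_polygon(data["polygon"], expected_dims)
    elif "rle" in data:
        mask = _rle_decode(data["rle"], expected_dims)
    else:
        raise ValidationError(f"ROI file {path} has neither 'polygon' nor 'rle'")
    if role == "artery" and not mask.any():
        raise ValidationError("artery ROI rasterized to an empty mask")
    return ROIMask(mask=mask, role=role)


def write_roi(roi: ROIMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"role": roi.role, "rle": _rle_encode(roi.mask)}, fh)


# ---------------------------------------------------------------------------
# map output
# ---------------------------------------------------------------------------


def write_maps(
    slope_map: SlopeMap, rgb_map: np.ndarray, out_prefix: str | Path
) -> dict[str, Path]:
    """Write the slope grid (float32 TIFF, NaN where invalid) and RGB PNG."""
    rgb_map = np.asarray(rgb_map)
    if rgb_map.shape[:2] != slope_map.slope.shape:
        raise ValidationError("rendered map and slope map must share dims")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    slope = slope_map.slope.astype(np.float32)
    slope = np.where(slope_map.valid, slope, np.float32(np.nan))
    tif_path = out_prefix.with_name(out_prefix.name + "_slope.tif")
    tifffile.imwrite(tif_path, slope)

    png_path = out_prefix.with_name(out_prefix.name + "_map.png")
    iio.imwrite(png_path, rgb_map.astype(np.uint8))
    return {"slope": tif_path, "map": png_path}


def read_slope_map(path: str | Path) -> SlopeMap:
    """Read a slope TIFF written by :func:`write_maps` (NaN marks invalid)."""
    slope = np.asarray(tifffile.imread(path), dtype=np.float64)
    valid = np.isfinite(slope)
    slope = np.where(valid, slope, 0.0)
    return SlopeMap(slope=slope, valid=valid, n_points=0)


# ---------------------------------------------------------------------------
# rater grid CSV
# ---------------------------------------------------------------------------

_SQ_COLS = [f"sq_{i}" for i in range(1, 10)]


def read_rater_grids(path: str | Path) -> list[RaterGrid]:
    """Read rater grids from CSV with columns rater_id,eye_id,sq_1..sq_9,overall."""
    df = pd.read_csv(path, dtype={"rater_id": str, "eye_id": str})
    missing = [c for c in ["rater_id", "eye_id", "overall", *_SQ_COLS] if c not in df]
    if missing:
        raise ValidationError(f"rater CSV missing columns: {missing}")
    grids = []
    for _, row in df.iterrows():
        grids.append(
            RaterGrid(
                squares=row[_SQ_COLS].to_numpy(dtype=int),
                overall=int(row["overall"]),
                rater_id=str(row["rater_id"]),
                eye_id=str(row["eye_id"]),
            )
        )
    return grids


def write_rater_grids(grids: Iterable[RaterGrid], path: str | Path) -> None:
    rows = []
    for g in grids:
        row = {"rater_id": g.rater_id, "eye_id": g.eye_id}
        row.update({c: v for c, v in zip(_SQ_COLS, g.squares.ravel())})
        row["overall"] = g.overall
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
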