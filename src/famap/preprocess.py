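"""Frame quality control and eye lateralization.

The optic disc is the brightest compact structure in a fundus angiogram, so
lateralization reduces to finding its center of mass and comparing the column
against the frame midline. Noisy or non-retinal frames are flagged by their
correlation against the pixel-wise median frame, which is robust to the
global intensity drift across the angiographic phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import label

from famap.io_model import FASequence, Frame, ValidationError

#: Frames correlating below this with the median frame are excluded.
DEFAULT_MIN_CORR = 0.5

#: Centroid columns within this fraction of the midline are "ambiguous".
MIDLINE_TOLERANCE = 0.02


@dataclass
class DiscDetection:
    """Optic-disc segmentation: intensity-weighted centroid plus its mask."""

    centroid: tuple[float, float]
    mask: np.ndarray


def detect_optic_disc(frame: Frame, percentile: float = 99.0) -> DiscDetection:
    """Locate the optic disc as the largest bright connected component.

    Pixels above the given intensity percentile are kept, the largest
    connected component is selected and its intensity-weighted center of
    mass returned. Scaling all intensities by a positive constant leaves
    the result unchanged.
    """
    img = frame.pixels
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise ValidationError("no disc signal: frame intensity is constant")
    thresh = np.percentile(img, percentile)
    bright = img > thresh
    if not bright.any():
        bright = img >= thresh  # percentile can coincide with the maximum
    labels = label(bright, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    component = labels == sizes.argmax()
    weights = img[component]
    rows, cols = np.nonzero(component)
    centroid = (
        float(np.average(rows, weights=weights)),
        float(np.average(cols, weights=weights)),
    )
    return DiscDetection(centroid=centroid, mask=component)


def classify_eye(
    sequence: FASequence, disc_side_is_eye_side: bool = True
) -> str:
    """Classify the sequence as ``"left"``/``"right"`` from disc position.

    The median disc-centroid column across usable frames is compared with
    the frame midline. Within ±2% of the midline the outcome is
    ``"ambiguous"`` rather than a guess. ``disc_side_is_eye_side`` flips
    the convention for cameras with mirrored display.
    """
    cols = []
    for i in sequence.usable_indices():
        try:
            cols.append(detect_optic_disc(sequence.frames[i]).centroid[1])
        except ValidationError:
            continue
    if not cols:
        raise ValidationError("optic disc not detectable in any usable frame")
    n_cols = sequence.pixel_dims[1]
    midline = (n_cols - 1) / 2.0
    offset = float(np.median(cols)) - midline
    if abs(offset) <= MIDLINE_TOLERANCE * n_cols:
        return "ambiguous"
    disc_right = offset > 0
    if disc_side_is_eye_side:
        return "right" if disc_right else "left"
    return "left" if disc_right else "right"


def flag_noisy_frames(
    sequence: FASequence, min_corr: float = DEFAULT_MIN_CORR
) -> FASequence:
    """Return a copy with low-quality frames flagged ``excluded``.

    Each frame is correlated (Pearson) with the pixel-wise median frame of
    the sequence; frames below ``min_corr`` are excluded from all downstream
    stages.
    """
    if len(sequence) < 3:
        raise ValidationError("need at least 3 frames to flag outliers")
    stack = sequence.as_stack()
    median = np.median(stack, axis=0)
    med_flat = median.ravel()
    med_centered = med_flat - med_flat.mean()
    med_norm = np.linalg.norm(med_centered)

    flagged = []
    eye = sequence.frames[0].eye
    for frame in sequence.frames:
        f_flat = frame.pixels.ravel()
        f_centered = f_flat - f_flat.mean()
        denom = np.linalg.norm(f_centered) * med_norm
        corr = float(f_centered @ med_centered / denom) if denom > 0 else 0.0
        quality = "ok" if corr >= min_corr else "excluded"
        flagged.append(replace(frame, quality=quality, eye=eye))

    result = FASequence(flagged)
    if not result.usable_indices():
        raise ValidationError(
            f"sequence unusable: every frame correlates below {min_corr}"
        )
    return result
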