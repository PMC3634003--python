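"""Sub-pixel rigid registration of an angiographic sequence.

Shift estimation uses phase correlation with upsampled-DFT refinement on
edge-enhanced (Laplacian-of-Gaussian filtered) frames. The sequence is
chained outward from a reference frame: the frames immediately before and
after the reference are registered first, then each further frame is
registered against its already-registered inward neighbor and the pairwise
shifts are composed cumulatively. Shifts are applied to the original,
unfiltered frames by Fourier phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from famap.io_model import FASequence, ShiftVector, ValidationError

DEFAULT_LOG_SIZE = 8
DEFAULT_LOG_SIGMA = 1.4
DEFAULT_UPSAMPLE = 100


def log_kernel(size: int = DEFAULT_LOG_SIZE, sigma: float = DEFAULT_LOG_SIGMA) -> np.ndarray:
    """Discrete Laplacian-of-Gaussian kernel, mean-subtracted to sum to zero.

    Even sizes are supported: sample points are centered on the kernel
    support (offsets ±0.5, ±1.5, ... for size 8).
    """
    if size < 3:
        raise ValidationError("kernel size must be >= 3")
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    offsets = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    x, y = np.meshgrid(offsets, offsets)
    r2 = x**2 + y**2
    s2 = sigma**2
    kernel = (r2 - 2.0 * s2) / (s2**2) * np.exp(-r2 / (2.0 * s2))
    kernel -= kernel.mean()  # exact zero-sum: constant regions map to 0
    return kernel


def log_filter(
    image: np.ndarray,
    size: int = DEFAULT_LOG_SIZE,
    sigma: float = DEFAULT_LOG_SIGMA,
) -> np.ndarray:
    """Convolve with the zero-sum LoG kernel, reflect padding at borders."""
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < size:
        raise ValidationError(
            f"image {image.shape} smaller than kernel size {size}"
        )
    return ndimage.convolve(image, log_kernel(size, sigma), mode="reflect")


def estimate_shift(
    reference_img: np.ndarray,
    moving_img: np.ndarray,
    upsample: int = DEFAULT_UPSAMPLE,
) -> ShiftVector:
    """Estimate the translation of ``moving_img`` relative to ``reference_img``.

    Returns the (row, col) offset such that translating the moving image by
    the negated offset maximizes its correlation with the reference; the
    offset is localized to ``1/upsample`` pixel via upsampled discrete-Fourier
    cross-correlation around the coarse phase-correlation peak.
    ``peak_corr`` is the Pearson correlation of the aligned images, clipped
    to [0, 1].
    """
    reference_img = np.asarray(reference_img, dtype=np.float64)
    moving_img = np.asarray(moving_img, dtype=np.float64)
    if reference_img.shape != moving_img.shape:
        raise ValidationError("images must share dimensions")
    if upsample < 1:
        raise ValidationError("upsample factor must be >= 1")
    if np.ptp(reference_img) == 0 or np.ptp(moving_img) == 0:
        raise ValidationError("zero-variance input to shift estimation")

    # skimage returns the shift to APPLY to the moving image; the offset of
    # the moving image relative to the reference is its negation.
    shift, _, _ = phase_cross_correlation(
        reference_img, moving_img, upsample_factor=upsample, normalization=None
    )
    d_row, d_col = float(-shift[0]), float(-shift[1])

    aligned = apply_shift(moving_img, ShiftVector(d_row, d_col))
    a = aligned.ravel() - aligned.mean()
    b = reference_img.ravel() - reference_img.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    corr = float(a @ b / denom) if denom > 0 else 0.0
    return ShiftVector(d_row, d_col, peak_corr=float(np.clip(corr, 0.0, 1.0)))


def apply_shift(image: np.ndarray, shift: ShiftVector) -> np.ndarray:
    """Translate an image by (-d_row, -d_col) via Fourier phase shift.

    Output dimensions are unchanged; content wraps circularly at the edges
    (masked out of analysis by a border margin downstream).
    """
    image = np.asarray(image, dtype=np.float64)
    spectrum = np.fft.fft2(image)
    shifted = ndimage.fourier_shift(spectrum, (-shift.d_row, -shift.d_col))
    return np.real(np.fft.ifft2(shifted))


def select_reference(sequence: FASequence) -> int:
    """Index of the usable frame most correlated with the usable-frame mean.

    Ties break toward the lowest index.
    """
    usable = sequence.usable_indices()
    if len(usable) < 2:
        raise ValidationError("need at least 2 usable frames")
    stack = sequence.as_stack(usable_only=True)
    mean_img = stack.mean(axis=0)
    m = mean_img.ravel() - mean_img.mean()
    m_norm = np.linalg.norm(m)

    best_idx, best_corr = usable[0], -np.inf
    for idx, img in zip(usable, stack):
        f = img.ravel() - img.mean()
        denom = np.linalg.norm(f) * m_norm
        corr = float(f @ m / denom) if denom > 0 else -np.inf
        if corr > best_corr:
            best_idx, best_corr = idx, corr
    return best_idx


@dataclass
class RegistrationResult:
    """Cumulative per-frame shifts plus the registered sequence."""

    shifts: dict[int, ShiftVector]
    reference_index: int
    registered: FASequence


def register_sequence(
    sequence: FASequence,
    upsample: int = DEFAULT_UPSAMPLE,
    log_size: int = DEFAULT_LOG_SIZE,
    log_sigma: float = DEFAULT_LOG_SIGMA,
) -> RegistrationResult:
    """Register every usable frame to the automatically chosen reference.

    Excluded frames receive no shift, remain excluded and are bypassed by
    the chain (each link connects to the nearest usable inward neighbor).
    Edge filtering is used only for estimation; registered pixel data derive
    solely from the original frames.
    """
    usable = sequence.usable_indices()
    if len(usable) < 2:
        raise ValidationError("need at least 2 usable frames to register")

    ref = select_reference(sequence)
    # Hann window after edge filtering: reflect-padded borders otherwise
    # anchor the correlation peak and bias the chain by ~0.1 px.
    rows, cols = sequence.pixel_dims
    window = np.outer(np.hanning(rows), np.hanning(cols))
    filtered = {
        i: log_filter(sequence.frames[i].pixels, log_size, log_sigma) * window
        for i in usable
    }

    ref_pos = usable.index(ref)
    # outward processing order over usable positions: ref-1, ref+1, ref-2, ...
    order: list[int] = []
    for step in range(1, len(usable)):
        for pos in (ref_pos - step, ref_pos + step):
            if 0 <= pos < len(usable) and pos not in order:
                order.append(pos)

    shifts: dict[int, ShiftVector] = {ref: ShiftVector(0.0, 0.0, 1.0)}
    for pos in order:
        idx = usable[pos]
        inner = usable[pos + 1] if pos < ref_pos else usable[pos - 1]
        try:
            pairwise = estimate_shift(filtered[inner], filtered[idx], upsample)
        except ValidationError as exc:
            raise ValidationError(f"frame {idx}: {exc}") from exc
        cum = shifts[inner]
        shifts[idx] = ShiftVector(
            cum.d_row + pairwise.d_row,
            cum.d_col + pairwise.d_col,
            peak_corr=pairwise.peak_corr,
        )

    registered_frames = []
    for i, frame in enumerate(sequence.frames):
        if i in shifts and i != ref:
            moved = apply_shift(frame.pixels, shifts[i])
            registered_frames.append(replace(frame, pixels=np.maximum(moved, 0.0)))
        else:
            registered_frames.append(replace(frame))

    return RegistrationResult(
        shifts=shifts,
        reference_index=ref,
        registered=FASequence(registered_frames),
    )
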