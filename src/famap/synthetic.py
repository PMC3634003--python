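"""Synthetic angiography phantom with known ground truth.

The phantom emulates a two-phase acquisition protocol (fast early phase,
slower late phase), indicator-dilution dye kinetics with recirculation, a
lateralized bright optic disc, arteries and delayed veins drawn as
parametric curves, tissue washout, Patlak-like regional dye accumulation
(leakage), inter-frame motion and additive sensor noise. Every random
choice flows through one seeded generator, so identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from famap.io_model import FASequence, Frame, ROIMask, ShiftVector, ValidationError

#: Log-uniform leak-rate range (normalized units/s) for simulated patients.
PATIENT_K_RANGE = (5e-4, 3e-3)


@dataclass
class PhantomSpec:
    """Parameters of one simulated angiography study."""

    dims: tuple[int, int] = (128, 128)
    duration_s: float = 600.0
    phase1_rate: float = 20.0  # frames/min
    phase1_end_s: float = 90.0
    phase2_rate: float = 5.0  # frames/min
    # arterial input: gamma-variate bolus plus recirculation plateau
    aif_t0: float = 8.0
    aif_alpha: float = 2.0
    aif_beta: float = 12.0
    aif_amplitude: float = 150.0
    recirc_frac: float = 0.45
    recirc_rise_s: float = 30.0
    recirc_decay_s: float = 600.0
    vein_delay_s: float = 4.0
    tissue_base: float = 0.4  # tissue signal as fraction of AIF
    tissue_washout_per_s: float = 2.5e-3
    disc_gain: float = 1.3
    background: float = 1.5  # static non-dye signal (camera units)
    leak_regions: list[tuple[np.ndarray, float]] = field(default_factory=list)
    motion_sd: float = 0.5  # random-walk step, px/frame
    noise_sd: float = 1.2  # additive Gaussian, camera units
    eye: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_rate <= 0 or self.phase2_rate <= 0:
            raise ValidationError("acquisition rates must be > 0")
        if self.phase1_end_s >= self.duration_s:
            raise ValidationError("phase1_end_s must precede duration_s")
        if self.aif_alpha <= 0 or self.aif_beta <= 0:
            raise ValidationError("gamma-variate alpha and beta must be > 0")
        for mask, k in self.leak_regions:
            if np.asarray(mask).shape != tuple(self.dims):
                raise ValidationError("leak mask dims do not match phantom dims")
            if k < 0:
                raise ValidationError("leak rate k must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth recorded alongside a generated phantom."""

    leak_map: np.ndarray
    true_shifts: list[ShiftVector]
    artery_mask: ROIMask
    vein_mask: ROIMask
    disc_mask: ROIMask
    tissue_mask: ROIMask


def align_truth(truth: PhantomTruth, reference_shift: ShiftVector) -> PhantomTruth:
    """Move truth masks into the coordinate frame of a registered sequence.

    Registration aligns every frame to the chosen reference, whose content
    sits at the reference's own motion offset relative to the static canvas
    the truth masks were drawn on. Rolling the masks by the (rounded)
    reference shift brings them into the registered coordinate frame;
    the sub-pixel residual is below half a pixel.
    """
    dr = int(round(reference_shift.d_row))
    dc = int(round(reference_shift.d_col))

    def roll(arr: np.ndarray) -> np.ndarray:
        return np.roll(arr, (dr, dc), axis=(0, 1))

    return PhantomTruth(
        leak_map=roll(truth.leak_map),
        true_shifts=truth.true_shifts,
        artery_mask=ROIMask(roll(truth.artery_mask.mask), truth.artery_mask.role),
        vein_mask=ROIMask(roll(truth.vein_mask.mask), truth.vein_mask.role),
        disc_mask=ROIMask(roll(truth.disc_mask.mask), truth.disc_mask.role),
        tissue_mask=ROIMask(roll(truth.tissue_mask.mask), truth.tissue_mask.role),
    )


def frame_times(spec: PhantomSpec) -> np.ndarray:
    """Acquisition times (s) under the two-phase protocol."""
    step1 = 60.0 / spec.phase1_rate
    phase1 = np.arange(0.0, spec.phase1_end_s, step1)
    step2 = 60.0 / spec.phase2_rate
    phase2 = np.arange(spec.phase1_end_s, spec.duration_s + 1e-9, step2)
    return np.concatenate([phase1, phase2])


def gamma_variate(
    t: float | np.ndarray, t0: float, alpha: float, beta: float, amplitude: float
) -> np.ndarray:
    """Gamma-variate bolus curve, normalized to peak ``amplitude``.

    Zero for t <= t0; otherwise
    ``amplitude * ((t - t0)/(alpha*beta))**alpha * exp(alpha - (t - t0)/beta)``,
    which peaks at ``t0 + alpha*beta`` with value ``amplitude``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValidationError("alpha and beta must be > 0")
    t = np.asarray(t, dtype=np.float64)
    dt = t - t0
    with np.errstate(invalid="ignore"):
        val = amplitude * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta)
    return np.where(dt <= 0, 0.0, val)


def aif_model(t: float | np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Arterial dye curve: gamma-variate bolus plus recirculation plateau."""
    t = np.asarray(t, dtype=np.float64)
    bolus = gamma_variate(t, spec.aif_t0, spec.aif_alpha, spec.aif_beta, spec.aif_amplitude)
    dt = t - spec.aif_t0
    with np.errstate(invalid="ignore", over="ignore"):
        recirc = (
            spec.aif_amplitude
            * spec.recirc_frac
            * (1.0 - np.exp(-dt / spec.recirc_rise_s))
            * np.exp(-dt / spec.recirc_decay_s)
        )
    return bolus + np.where(dt <= 0, 0.0, recirc)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _stamp_curves(
    dims: tuple[int, int],
    center: tuple[float, float],
    angles_deg: list[float],
    curvatures: list[float],
    width_sigma: float,
    inner_radius: float,
) -> np.ndarray:
    """Render radial curves from the disc as a soft-edged profile in [0, 1]."""
    canvas = np.zeros(dims)
    max_r = float(np.hypot(*dims))
    s = np.arange(inner_radius, max_r, 0.5)
    for angle, curv in zip(angles_deg, curvatures):
        theta = np.deg2rad(angle) + curv * s / max_r
        rr = center[0] + s * np.sin(theta)
        cc = center[1] + s * np.cos(theta)
        ri = np.round(rr).astype(int)
        ci = np.round(cc).astype(int)
        keep = (ri >= 0) & (ri < dims[0]) & (ci >= 0) & (ci < dims[1])
        canvas[ri[keep], ci[keep]] = 1.0
    profile = ndimage.gaussian_filter(canvas, width_sigma)
    peak = profile.max()
    return profile / peak if peak > 0 else profile


def _phantom_geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    rows, cols = spec.dims
    lateral = 0.72 if spec.eye == "right" else 0.28
    disc_center = (rows * 0.5, cols * lateral)
    disc_radius = 0.06 * min(rows, cols)

    rr, cc = np.mgrid[0:rows, 0:cols]
    d = np.hypot(rr - disc_center[0], cc - disc_center[1])
    disc_profile = np.clip(1.5 * np.exp(-((d / disc_radius) ** 4)), 0.0, 1.0)

    spread = 180.0 if spec.eye == "right" else 0.0
    # angle sets symmetric about the horizontal axis: when one vessel class
    # brightens relative to the other the pattern centroid stays put, which
    # keeps transit-phase kinetics from masquerading as vertical motion
    artery_angles = [spread + a for a in (-90.0, -55.0, -20.0, 20.0, 55.0, 90.0)]
    vein_angles = [spread + a for a in (-98.0, -65.0, -34.0, 34.0, 65.0, 98.0)]
    arteries = _stamp_curves(
        spec.dims,
        disc_center,
        artery_angles,
        [1.1, -0.8, 0.9, -0.9, 0.8, -1.1],
        1.1,
        disc_radius * 0.8,
    )
    veins = _stamp_curves(
        spec.dims,
        disc_center,
        vein_angles,
        [-0.9, 1.0, -0.8, 0.8, -1.0, 0.9],
        1.3,
        disc_radius * 0.8,
    )
    # vessels do not overlap the disc blob; arteries shadow veins at crossings
    arteries = arteries * (1.0 - disc_profile)
    veins = veins * (1.0 - disc_profile) * (arteries < 0.25)
    tissue = np.clip(1.0 - arteries - veins - disc_profile, 0.0, 1.0)
    return {
        "disc_center": np.asarray(disc_center),
        "disc": disc_profile,
        "artery": arteries,
        "vein": veins,
        "tissue": tissue,
    }


def _pure_tissue(geo: dict[str, np.ndarray], margin_px: int = 3) -> np.ndarray:
    """Tissue pixels at least ``margin_px`` away from any vascular structure.

    Sub-pixel resampling mixes vessel signal into the immediate neighbors of
    an edge, so ground-truth "tissue" excludes a partial-volume margin.
    """
    vascular = (geo["artery"] > 0.02) | (geo["vein"] > 0.02) | (geo["disc"] > 0.02)
    vascular = ndimage.binary_dilation(vascular, iterations=margin_px)
    return (geo["tissue"] > 0.95) & ~vascular


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[FASequence, PhantomTruth]:
    """Render the phantom sequence and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    times = frame_times(spec)
    geo = _phantom_geometry(spec)

    leak_map = np.zeros(spec.dims)
    for mask, k in spec.leak_regions:
        leak_map = np.maximum(leak_map, np.asarray(mask, dtype=bool) * k)

    # dye curves on a fine grid for the cumulative integral
    fine_t = np.arange(0.0, spec.duration_s + 1.0, 0.5)
    fine_aif = aif_model(fine_t, spec)
    fine_cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (fine_aif[1:] + fine_aif[:-1]) * np.diff(fine_t))]
    )

    aif_t = aif_model(times, spec)
    vein_t = aif_model(times - spec.vein_delay_s, spec)
    cum_t = np.interp(times, fine_t, fine_cum)
    washout = np.exp(-spec.tissue_washout_per_s * np.maximum(times - spec.aif_t0, 0.0))

    background = spec.background * np.clip(
        1.0 + 0.3 * ndimage.gaussian_filter(rng.standard_normal(spec.dims), 6.0) * 8.0,
        0.2,
        2.0,
    )

    # inter-frame motion: random walk of sub-pixel translations
    steps = rng.normal(0.0, spec.motion_sd, size=(len(times), 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)

    frames = []
    true_shifts = []
    for i, t in enumerate(times):
        img = (
            background
            + geo["artery"] * aif_t[i]
            + geo["vein"] * vein_t[i]
            + geo["disc"] * spec.disc_gain * aif_t[i]
            + geo["tissue"]
            * (spec.tissue_base * aif_t[i] * washout[i] + leak_map * cum_t[i])
        )
        d_row, d_col = walk[i]
        if d_row != 0.0 or d_col != 0.0:
            img = np.real(
                np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (d_row, d_col)))
            )
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=spec.dims)
        frames.append(Frame(np.maximum(img, 0.0), t=float(t), eye=spec.eye))
        true_shifts.append(ShiftVector(float(d_row), float(d_col), peak_corr=1.0))

    truth = PhantomTruth(
        leak_map=leak_map,
        true_shifts=true_shifts,
        artery_mask=ROIMask(geo["artery"] > 0.35, "artery"),
        vein_mask=ROIMask(geo["vein"] > 0.35, "other"),
        disc_mask=ROIMask(geo["disc"] > 0.05, "optic_disc"),
        tissue_mask=ROIMask(_pure_tissue(geo), "other"),
    )
    return FASequence(frames), truth


def _random_leak_regions(
    spec: PhantomSpec, rng: np.random.Generator, n_regions: int
) -> list[tuple[np.ndarray, float]]:
    rows, cols = spec.dims
    rr, cc = np.mgrid[0:rows, 0:cols]
    regions = []
    lo, hi = PATIENT_K_RANGE
    for _ in range(n_regions):
        radius = rng.uniform(0.07, 0.14) * min(rows, cols)
        r0 = rng.uniform(radius + 2, rows - radius - 2)
        c0 = rng.uniform(radius + 2, cols - radius - 2)
        mask = np.hypot(rr - r0, cc - c0) <= radius
        k = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        regions.append((mask, k))
    return regions


def generate_cohort(
    base_spec: PhantomSpec,
    n_healthy: int,
    n_patient: int,
    seed: int,
) -> list[tuple[FASequence, PhantomTruth]]:
    """Simulate a cohort: healthy eyes (k = 0) then patient eyes with leaks.

    Per-subject seeds and parameter jitter derive deterministically from the
    master seed, so reruns reproduce the cohort exactly.
    """
    if n_healthy < 0 or n_patient < 0:
        raise ValidationError("cohort sizes must be >= 0")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_healthy + n_patient):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        amplitude = base_spec.aif_amplitude * rng.uniform(0.85, 1.15)
        spec = replace(
            base_spec,
            seed=sub_seed,
            aif_amplitude=float(amplitude),
            eye="right" if rng.random() < 0.5 else "left",
            leak_regions=[],
        )
        if i >= n_healthy:
            n_regions = int(rng.integers(1, 5))
            spec.leak_regions = _random_leak_regions(spec, rng, n_regions)
        subjects.append(generate_phantom(spec))
    return subjects
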