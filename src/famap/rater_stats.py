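"""Inter-rater agreement and diagnostic-accuracy statistics.

Implements Fleiss' kappa for multiple raters on binary calls, a paired
bootstrap for the difference of two correlated kappas, rater-averaged
sensitivity/specificity against a gold-standard vector, 3x3-grid consensus
scoring with a per-eye median, and the exact one-tailed McNemar test on
discordant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from famap.io_model import RaterGrid, ValidationError

#: Landis & Koch interpretation bands for kappa values.
_KAPPA_BANDS = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.01, "almost perfect"),
]


def kappa_label(kappa: float) -> str:
    """Agreement band (Landis & Koch) for a kappa value."""
    if not np.isfinite(kappa):
        return "degenerate"
    for upper, name in _KAPPA_BANDS:
        if kappa < upper:
            return name
    return "almost perfect"


@dataclass
class RatingTable:
    """Subjects x raters binary matrix (1 = pathologic)."""

    ratings: np.ndarray
    modality: str = "FA"

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=int)
        if self.ratings.ndim != 2:
            raise ValidationError("ratings must be a 2-D subjects x raters matrix")
        n_subjects, n_raters = self.ratings.shape
        if n_subjects < 2 or n_raters < 2:
            raise ValidationError("need >= 2 subjects and >= 2 raters")
        if not np.isin(self.ratings, (0, 1)).all():
            raise ValidationError("ratings must be binary (0/1) with no missing cells")

    @property
    def n_subjects(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]


@dataclass
class KappaResult:
    kappa: float
    degenerate: bool
    label: str


def fleiss_kappa(table: RatingTable) -> KappaResult:
    """Fleiss' kappa for binary ratings.

    kappa = (P_bar - P_e) / (1 - P_e) with per-subject observed agreement
    P_bar and chance agreement P_e from the marginal category proportions.
    When every rating falls in a single category P_e = 1 and kappa is
    undefined; the result is flagged degenerate with kappa = NaN.
    """
    r = table.ratings
    n = table.n_raters
    counts = np.stack([(r == 0).sum(axis=1), (r == 1).sum(axis=1)], axis=1)

    p_j = counts.sum(axis=0) / (table.n_subjects * n)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-15:
        return KappaResult(kappa=float("nan"), degenerate=True, label="degenerate")

    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), degenerate=False, label=kappa_label(kappa))


@dataclass
class BootstrapKappaDiff:
    diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int


def bootstrap_kappa_diff(
    table_a: RatingTable,
    table_b: RatingTable,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> BootstrapKappaDiff:
    """Percentile 95% CI for kappa(b) - kappa(a) on paired tables.

    Subjects are resampled with replacement jointly across the two
    modalities, preserving the pairing. Replicates where either kappa is
    degenerate are dropped; if that affects more than 10% of replicates a
    warning is issued.
    """
    if table_a.n_subjects != table_b.n_subjects:
        raise ValidationError("paired tables must share subjects")
    if n_boot < 1000:
        raise ValidationError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    n = table_a.n_subjects

    point = fleiss_kappa(table_b).kappa - fleiss_kappa(table_a).kappa

    diffs = np.empty(n_boot)
    n_degenerate = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ka = fleiss_kappa(RatingTable(table_a.ratings[idx], table_a.modality))
        kb = fleiss_kappa(RatingTable(table_b.ratings[idx], table_b.modality))
        if ka.degenerate or kb.degenerate:
            n_degenerate += 1
            continue
        diffs[kept] = kb.kappa - ka.kappa
        kept += 1
    if n_degenerate > 0.1 * n_boot:
        warnings.warn(
            f"{n_degenerate}/{n_boot} bootstrap replicates were degenerate "
            "and dropped",
            stacklevel=2,
        )
    if kept == 0:
        raise ValidationError("every bootstrap replicate was degenerate")
    lo, hi = np.percentile(diffs[:kept], [2.5, 97.5])
    return BootstrapKappaDiff(
        diff=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_degenerate=n_degenerate,
    )


@dataclass
class SensSpec:
    sensitivity: float
    specificity: float
    per_rater: list[tuple[float, float]]
    defined: bool = True


def sens_spec(table: RatingTable, gold: np.ndarray) -> SensSpec:
    """Per-rater sensitivity/specificity vs gold, averaged over raters.

    If the gold standard has no positives (or no negatives) the affected
    rate is undefined; the result carries NaN and ``defined=False``.
    """
    gold = np.asarray(gold, dtype=int)
    if gold.shape != (table.n_subjects,):
        raise ValidationError("gold must be a binary vector over subjects")
    pos = gold == 1
    neg = ~pos

    per_rater = []
    for j in range(table.n_raters):
        calls = table.ratings[:, j]
        sens = float((calls[pos] == 1).mean()) if pos.any() else float("nan")
        spec = float((calls[neg] == 0).mean()) if neg.any() else float("nan")
        per_rater.append((sens, spec))

    arr = np.asarray(per_rater)
    defined = bool(pos.any() and neg.any())
    return SensSpec(
        sensitivity=float(arr[:, 0].mean()),
        specificity=float(arr[:, 1].mean()),
        per_rater=per_rater,
        defined=defined,
    )


@dataclass
class ConsensusRecord:
    """Per-square consensus scores for one eye plus their median."""

    eye_id: str
    square_scores: np.ndarray
    eye_score: float

    def __post_init__(self) -> None:
        self.square_scores = np.asarray(self.square_scores, dtype=float).ravel()
        if self.square_scores.size != 9:
            raise ValidationError("exactly 9 square scores required")


def consensus_score(grids_for_eye: list[RaterGrid]) -> ConsensusRecord:
    """Score each grid square 1 when all raters agree (either way), else 0.

    The eye-level score is the median of the 9 square scores; with an odd
    square count it is always 0 or 1.
    """
    if len(grids_for_eye) != 3:
        raise ValidationError(
            f"expected one grid per rater (3), got {len(grids_for_eye)}"
        )
    eye_ids = {g.eye_id for g in grids_for_eye}
    if len(eye_ids) != 1:
        raise ValidationError(f"grids must refer to one eye, got {sorted(eye_ids)}")
    calls = np.stack([g.squares.ravel() for g in grids_for_eye])
    scores = (calls.max(axis=0) == calls.min(axis=0)).astype(float)
    return ConsensusRecord(
        eye_id=grids_for_eye[0].eye_id,
        square_scores=scores,
        eye_score=float(np.median(scores)),
    )


def mcnemar_one_tailed(
    paired_outcomes: np.ndarray, exact: bool = True
) -> float:
    """One-tailed McNemar p-value on paired binary outcomes.

    ``paired_outcomes`` is an (N, 2) array of (first, second) binary
    outcomes per subject. With b = pairs improving under the second
    condition and c = pairs worsening, the exact form is the binomial tail
    P(X >= b | n = b + c, theta = 0.5); ``exact=False`` gives the
    continuity-corrected chi-square alternative (halved for one tail).
    Zero discordant pairs yield p = 1.0.
    """
    paired = np.asarray(paired_outcomes, dtype=int)
    if paired.ndim != 2 or paired.shape[1] != 2:
        raise ValidationError("paired outcomes must be an (N, 2) binary array")
    first, second = paired[:, 0], paired[:, 1]
    b = int(((second == 1) & (first == 0)).sum())
    c = int(((second == 0) & (first == 1)).sum())
    n = b + c
    if n == 0:
        return 1.0
    if exact:
        return float(stats.binom.sf(b - 1, n, 0.5))
    chi2 = (abs(b - c) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1) / 2.0)
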