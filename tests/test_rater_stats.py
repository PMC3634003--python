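import numpy as np
import pytest
from scipy import stats as sps

from famap.io_model import RaterGrid, ValidationError
from famap.rater_stats import (
    RatingTable,
    bootstrap_kappa_diff,
    consensus_score,
    fleiss_kappa,
    kappa_label,
    mcnemar_one_tailed,
    sens_spec,
)


def _kappa_by_summation(ratings):
    """Independent oracle: Fleiss' kappa by explicit summation."""
    n_subjects, n_raters = ratings.shape
    counts = np.zeros((n_subjects, 2))
    for i in range(n_subjects):
        for j in range(n_raters):
            counts[i, ratings[i, j]] += 1
    p_j = counts.sum(axis=0) / (n_subjects * n_raters)
    p_e = sum(p**2 for p in p_j)
    p_i = [
        (sum(c**2 for c in counts[i]) - n_raters) / (n_raters * (n_raters - 1))
        for i in range(n_subjects)
    ]
    p_bar = sum(p_i) / n_subjects
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    def test_unanimous_mixed_categories(self):
        ratings = np.array([[i % 2] * 3 for i in range(10)])
        result = fleiss_kappa(RatingTable(ratings))
        assert result.kappa == pytest.approx(1.0)
        assert result.label == "almost perfect"

    def test_chance_level_simulation(self):
        rng = np.random.default_rng(99)
        ratings = rng.integers(0, 2, size=(10_000, 3))
        result = fleiss_kappa(RatingTable(ratings))
        assert abs(result.kappa) < 0.02

    def test_matches_summation_oracle_on_random_tables(self, rng):
        for _ in range(50):
            ratings = rng.integers(0, 2, size=(4, 3))
            table_kappa = fleiss_kappa(RatingTable(ratings))
            if table_kappa.degenerate:
                assert len(np.unique(ratings)) == 1
                continue
            assert table_kappa.kappa == pytest.approx(
                _kappa_by_summation(ratings), rel=1e-12
            )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        ratings = rng.integers(0, 2, size=(30, 4))
        counts, _ = aggregate_raters(ratings)
        assert fleiss_kappa(RatingTable(ratings)).kappa == pytest.approx(
            sm_fleiss(counts), rel=1e-10
        )

    def test_single_category_degenerate(self):
        result = fleiss_kappa(RatingTable(np.ones((5, 3), dtype=int)))
        assert result.degenerate
        assert np.isnan(result.kappa)

    def test_category_relabel_invariance(self, rng):
        ratings = rng.integers(0, 2, size=(12, 3))
        a = fleiss_kappa(RatingTable(ratings)).kappa
        b = fleiss_kappa(RatingTable(1 - ratings)).kappa
        assert a == pytest.approx(b, rel=1e-12)

    def test_subject_permutation_invariance(self, rng):
        ratings = rng.integers(0, 2, size=(12, 3))
        perm = rng.permutation(12)
        a = fleiss_kappa(RatingTable(ratings)).kappa
        b = fleiss_kappa(RatingTable(ratings[perm])).kappa
        assert a == pytest.approx(b, rel=1e-12)

    def test_labels(self):
        assert kappa_label(0.5) == "moderate"
        assert kappa_label(0.7) == "substantial"
        assert kappa_label(0.795) == "substantial"
        assert kappa_label(0.857) == "almost perfect"


class TestBootstrapKappaDiff:
    def _paired_tables(self, rng, n=30):
        latent = rng.integers(0, 2, size=n)
        noisy = lambda flip: np.column_stack(
            [
                np.where(rng.random(n) < flip, 1 - latent, latent)
                for _ in range(3)
            ]
        )
        return RatingTable(noisy(0.15), "FA"), RatingTable(noisy(0.15), "map")

    def test_identical_tables_zero_diff(self, rng):
        table = RatingTable(rng.integers(0, 2, size=(20, 3)))
        result = bootstrap_kappa_diff(table, table, n_boot=1000, seed=5)
        assert result.diff == 0.0
        assert result.ci_low <= 0.0 <= result.ci_high

    def test_seed_determinism(self, rng):
        a, b = self._paired_tables(rng)
        r1 = bootstrap_kappa_diff(a, b, n_boot=1000, seed=7)
        r2 = bootstrap_kappa_diff(a, b, n_boot=1000, seed=7)
        assert (r1.ci_low, r1.ci_high, r1.diff) == (r2.ci_low, r2.ci_high, r2.diff)

    def test_ci_coverage_on_null(self):
        # same generating process for both tables -> true kappa diff is 0
        rng = np.random.default_rng(2024)
        covered = 0
        n_sim = 120
        for _ in range(n_sim):
            a, b = self._paired_tables(rng)
            r = bootstrap_kappa_diff(a, b, n_boot=1000, seed=int(rng.integers(1e6)))
            covered += r.ci_low <= 0.0 <= r.ci_high
        assert covered / n_sim >= 0.85

    def test_n_boot_floor(self, rng):
        a, b = self._paired_tables(rng)
        with pytest.raises(ValidationError):
            bootstrap_kappa_diff(a, b, n_boot=10, seed=1)


class TestSensSpec:
    def test_perfect_raters(self):
        gold = np.array([1, 1, 0, 0])
        table = RatingTable(np.column_stack([gold, gold]))
        result = sens_spec(table, gold)
        assert (result.sensitivity, result.specificity) == (1.0, 1.0)

    def test_confusion_count_oracle(self):
        gold = np.array([1, 1, 0, 0])
        ratings = np.column_stack([[1, 0, 0, 0], [1, 0, 0, 0]])
        result = sens_spec(RatingTable(ratings), gold)
        assert result.sensitivity == pytest.approx(0.5)
        assert result.specificity == pytest.approx(1.0)

    def test_average_over_raters(self):
        gold = np.array([1, 1, 0, 0])
        ratings = np.column_stack([[1, 1, 0, 0], [1, 0, 0, 0]])
        result = sens_spec(RatingTable(ratings), gold)
        assert result.sensitivity == pytest.approx(0.75)

    def test_average_within_per_rater_range(self, rng):
        gold = rng.integers(0, 2, size=20)
        gold[:2] = [0, 1]  # both classes present
        table = RatingTable(rng.integers(0, 2, size=(20, 4)))
        result = sens_spec(table, gold)
        sens = [s for s, _ in result.per_rater]
        spec = [s for _, s in result.per_rater]
        assert min(sens) <= result.sensitivity <= max(sens)
        assert min(spec) <= result.specificity <= max(spec)

    def test_no_positives_undefined(self):
        gold = np.zeros(4, dtype=int)
        table = RatingTable(np.zeros((4, 2), dtype=int))
        result = sens_spec(table, gold)
        assert not result.defined
        assert np.isnan(result.sensitivity)


class TestConsensusScore:
    def _grids(self, squares_list, eye="e1"):
        return [
            RaterGrid(np.asarray(s), overall=1, rater_id=f"r{i}", eye_id=eye)
            for i, s in enumerate(squares_list)
        ]

    def test_identical_grids_median_one(self):
        s = [1, 0, 1, 0, 1, 0, 1, 0, 1]
        rec = consensus_score(self._grids([s, s, s]))
        assert rec.square_scores.sum() == 9
        assert rec.eye_score == 1.0

    def test_one_square_disagreement(self):
        a = [1, 0, 1, 0, 1, 0, 1, 0, 1]
        b = list(a)
        b[4] = 1 - b[4]
        rec = consensus_score(self._grids([a, a, b]))
        assert rec.square_scores.sum() == 8
        assert rec.eye_score == 1.0

    def test_five_square_disagreement_median_zero(self):
        a = [0] * 9
        b = [1, 1, 1, 1, 1, 0, 0, 0, 0]
        rec = consensus_score(self._grids([a, a, b]))
        assert rec.square_scores.sum() == 4
        assert rec.eye_score == 0.0

    def test_rater_symmetry(self, rng):
        grids = self._grids([rng.integers(0, 2, 9) for _ in range(3)])
        base = consensus_score(grids)
        swapped = consensus_score([grids[2], grids[0], grids[1]])
        np.testing.assert_array_equal(base.square_scores, swapped.square_scores)

    def test_unanimous_absence_scores_one(self):
        rec = consensus_score(self._grids([[0] * 9] * 3))
        assert rec.eye_score == 1.0

    def test_missing_rater_errors(self):
        with pytest.raises(ValidationError):
            consensus_score(self._grids([[0] * 9] * 2))

    def test_mixed_eyes_error(self):
        grids = self._grids([[0] * 9] * 2) + self._grids([[0] * 9], eye="e2")
        with pytest.raises(ValidationError):
            consensus_score(grids)


class TestMcNemar:
    def _paired(self, b, c, n_same=10):
        rows = [[0, 0]] * n_same + [[0, 1]] * b + [[1, 0]] * c
        return np.asarray(rows)

    def test_b5_c0(self):
        assert mcnemar_one_tailed(self._paired(5, 0)) == pytest.approx(0.03125)

    def test_b3_c3(self):
        assert mcnemar_one_tailed(self._paired(3, 3)) == pytest.approx(0.65625)

    def test_no_discordant_pairs(self):
        assert mcnemar_one_tailed(self._paired(0, 0)) == 1.0

    def test_matches_binomial_enumeration_all_n(self):
        for n in range(1, 26):
            for b in range(n + 1):
                c = n - b
                p = mcnemar_one_tailed(self._paired(b, c))
                exact = sum(sps.binom.pmf(k, n, 0.5) for k in range(b, n + 1))
                assert p == pytest.approx(exact, rel=1e-9), (b, c)

    def test_chi2_variant(self):
        p = mcnemar_one_tailed(self._paired(15, 5), exact=False)
        chi2 = (abs(15 - 5) - 1) ** 2 / 20
        assert p == pytest.approx(sps.chi2.sf(chi2, 1) / 2)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            mcnemar_one_tailed(np.zeros((4, 3)))
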