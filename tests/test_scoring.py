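import numpy as np
import pandas as pd
import pytest

import stromabalance as sb
from stromabalance.genesets import StromaGeneSets
from stromabalance.io import GeneSet

from conftest import matrix_from


def brute_force_es(sample: pd.Series, members: set) -> float:
    """Independent running-sum oracle: explicit loop over the ranked genes."""
    ordered = sorted(sample.index, key=lambda g: (-sample[g], g))
    n, nh = len(ordered), len(members)
    running, best = 0.0, 0.0
    for g in ordered:
        running += 1.0 / nh if g in members else -1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def series(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=genes)


class TestSingleSampleES:
    def test_top_ranked_singleton_reaches_plus_one(self):
        s = series([4.0, 3.0, 2.0, 1.0])
        assert sb.single_sample_es(s, ["g0"]) == pytest.approx(1.0)

    def test_bottom_ranked_singleton_reaches_minus_one(self):
        s = series([4.0, 3.0, 2.0, 1.0])
        assert sb.single_sample_es(s, ["g3"]) == pytest.approx(-1.0)

    def test_constant_shift_invariance(self, rng):
        s = series(rng.normal(size=30))
        genes = list(rng.choice(s.index, size=8, replace=False))
        assert sb.single_sample_es(s, genes) == sb.single_sample_es(s + 7.5, genes)

    def test_matches_brute_force_oracle_on_random_universes(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, n))
            s = series(rng.normal(size=n))
            if rng.random() < 0.3:  # exercise tie handling
                s = s.round(1)
            members = set(rng.choice(s.index, size=k, replace=False))
            assert sb.single_sample_es(s, members) == pytest.approx(
                brute_force_es(s, members)
            )

    def test_antisymmetric_under_rank_reversal(self, rng):
        # tie-free profile: reversing the ranking negates the score; when the
        # positive peak and negative trough of the running sum tie exactly in
        # magnitude only the magnitude is preserved (the sign tie-break picks
        # the first extremum in each direction of the walk)
        for _ in range(50):
            n = int(rng.integers(6, 50))
            vals = rng.permutation(n).astype(float)
            s = series(vals)
            members = set(rng.choice(s.index, size=int(rng.integers(1, n - 1)), replace=False))
            fwd = sb.single_sample_es(s, members)
            rev = sb.single_sample_es(-s, members)
            assert abs(rev) == pytest.approx(abs(fwd))
            steps = np.where(np.isin(sorted(s.index, key=lambda g: (-s[g], g)), list(members)),
                             1.0 / len(members), -1.0 / (n - len(members)))
            running = np.cumsum(steps)
            if not np.isclose(running.max(), -running.min()):
                assert rev == pytest.approx(-fwd)

    def test_rejects_degenerate_sets(self):
        s = series([3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            sb.single_sample_es(s, [])
        with pytest.raises(ValueError):
            sb.single_sample_es(s, ["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="absent"):
            sb.single_sample_es(s, ["nope"])


def toy_sets(universe, k):
    up = GeneSet("up", "", tuple(universe[:k]))
    down = GeneSet("down", "", tuple(universe[-k:]))
    return StromaGeneSets(up, down, n_top=k, source="toy")


class TestStromaScoreCohort:
    def test_two_sample_normalization_spans_0_100(self, rng):
        values = rng.normal(size=(40, 2))
        m = matrix_from(values)
        sets = toy_sets(m.gene_ids, 5)
        table = sb.stroma_score_cohort(m, sets, sizes=(3, 5))
        assert sorted(table.stroma_score) == [0.0, 100.0]
        assert np.allclose(table.normalized.min(axis=0), 0.0)
        assert np.allclose(table.normalized.max(axis=0), 100.0)

    def test_single_sample_cohort_scores_50_with_warning(self, rng):
        m = matrix_from(rng.normal(size=(30, 1)))
        sets = toy_sets(m.gene_ids, 4)
        with pytest.warns(UserWarning, match="single-sample"):
            table = sb.stroma_score_cohort(m, sets, sizes=(2, 4))
        assert table.stroma_score.iloc[0] == pytest.approx(50.0)

    def test_monotone_per_sample_transform_invariance(self, rng):
        values = rng.normal(size=(60, 8))
        m1 = matrix_from(values)
        transformed = np.exp(values * 0.5) + 3.0  # strictly increasing
        m2 = matrix_from(transformed)
        sets = toy_sets(m1.gene_ids, 10)
        t1 = sb.stroma_score_cohort(m1, sets, sizes=(5, 10))
        t2 = sb.stroma_score_cohort(m2, sets, sizes=(5, 10))
        pd.testing.assert_series_equal(t1.stroma_score, t2.stroma_score)

    @pytest.fixture()
    def derived_sets(self, small_cohort):
        ann = small_cohort.annotation
        cls = ann.set_index("sample_id")["class"]
        strat = sb.split_by_stroma(ann, ann.set_index("sample_id")["stroma_pct"])
        m = small_cohort.matrix
        de_bal = sb.mann_whitney_de(sb.ExpressionMatrix(m.data[list(strat.balanced)], "s"), cls)
        de_unbal = sb.mann_whitney_de(sb.ExpressionMatrix(m.data[list(strat.unbalanced)], "s"), cls)
        return sb.build_stroma_genesets(de_bal, de_unbal, n_top=60)

    def test_score_correlates_with_true_stroma_fraction(self, small_cohort, derived_sets):
        table = sb.stroma_score_cohort(small_cohort.matrix, derived_sets, sizes=(20, 40, 60))
        truth = small_cohort.truth.tissue_fractions["stroma"]
        r = np.corrcoef(table.stroma_score.reindex(truth.index), truth)[0, 1]
        assert r >= 0.85

    def test_size_ladder_robustness(self, small_cohort, derived_sets):
        # a 2-size ladder tracks the full ladder's sample ordering once the
        # sets carry real stroma signal
        from scipy.stats import spearmanr

        m = small_cohort.matrix
        full = sb.stroma_score_cohort(m, derived_sets, sizes=(10, 20, 30, 40, 50, 60))
        short = sb.stroma_score_cohort(m, derived_sets, sizes=(10, 60))
        rho = spearmanr(full.stroma_score, short.stroma_score.reindex(full.sample_ids)).statistic
        assert rho >= 0.95

    def test_size_and_universe_guards(self, rng):
        m = matrix_from(rng.normal(size=(20, 3)))
        sets = toy_sets(m.gene_ids, 5)
        with pytest.raises(ValueError, match="size"):
            sb.stroma_score_cohort(m, sets, sizes=(6,))
        with pytest.raises(ValueError, match="universe"):
            sb.stroma_score_cohort(m, sets, sizes=(5,), universe=m.gene_ids[:8])


class TestCalibration:
    def test_exact_linear_fit_recovered(self):
        score = pd.Series([10.0, 20.0, 40.0, 70.0], index=list("abcd"))
        histo = 2.0 * score + 5.0
        model = sb.calibrate_to_histopathology(score, histo)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(5.0)
        assert model.pearson_r == pytest.approx(1.0)
        assert model.mean_abs_deviation == pytest.approx(0.0, abs=1e-9)

    def test_predictions_clipped_to_percentage_range(self):
        model = sb.CalibrationModel(slope=2.0, intercept=5.0, pearson_r=1.0, mean_abs_deviation=0.0)
        assert model.predict([-10.0, 100.0]).tolist() == [0.0, 100.0]

    def test_uncorrelated_inputs_give_near_zero_r(self, rng):
        idx = [f"s{i}" for i in range(200)]
        score = pd.Series(rng.normal(size=200), index=idx)
        histo = pd.Series(rng.uniform(0, 100, size=200), index=idx)
        model = sb.calibrate_to_histopathology(score, histo)
        assert abs(model.pearson_r) < 0.2

    def test_constant_scores_rejected(self):
        score = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        histo = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            sb.calibrate_to_histopathology(score, histo)


class TestScoreStability:
    def test_identical_scores_across_sizes_have_zero_sd(self, rng):
        m = matrix_from(rng.normal(size=(30, 4)))
        sets = toy_sets(m.gene_ids, 5)
        sd, mean_sd = sb.score_stability(m, sets, sizes=(5, 5, 5))
        assert np.allclose(sd, 0.0) and mean_sd == pytest.approx(0.0)

    def test_sd_matches_normalized_table(self, rng):
        m = matrix_from(rng.normal(size=(50, 6)))
        sets = toy_sets(m.gene_ids, 10)
        sizes = (4, 7, 10)
        sd, mean_sd = sb.score_stability(m, sets, sizes=sizes)
        table = sb.stroma_score_cohort(m, sets, sizes=sizes)
        expected = table.normalized.std(axis=1, ddof=1)
        assert np.allclose(sd, expected)
        # two-point closed form: SD of (40, 60) is 20/sqrt(2) = 14.14
        assert pd.Series([40.0, 60.0]).std() == pytest.approx(14.1421356)
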