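import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import stromabalance as sb
from stromabalance.meta import rank_normalize, weighted_mean_center

from conftest import matrix_from


class TestRankNormalize:
    def test_three_distinct_values(self):
        assert np.allclose(rank_normalize([5.0, 7.0, 9.0]), [0.0, 50.0, 100.0])

    def test_tied_minimum_uses_average_ranks(self):
        assert np.allclose(rank_normalize([5.0, 5.0, 9.0]), [25.0, 25.0, 100.0])

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=40)
        assert np.allclose(rank_normalize(v), rank_normalize(np.exp(v)))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_normalize([1.0])

    def test_matrix_rows_span_0_100_without_total_ties(self, rng):
        scores = rank_normalize(rng.normal(size=(30, 12)))
        assert np.allclose(scores.min(axis=1), 0.0)
        assert np.allclose(scores.max(axis=1), 100.0)


class TestWeightedMeanCenter:
    def frame(self, cancer_vals, normal_vals):
        cols = [f"c{i}" for i in range(len(cancer_vals))] + [
            f"n{i}" for i in range(len(normal_vals))
        ]
        classes = pd.Series(
            ["cancer"] * len(cancer_vals) + ["normal"] * len(normal_vals), index=cols
        )
        scores = pd.DataFrame([list(cancer_vals) + list(normal_vals)], columns=cols)
        return scores, classes

    def test_hand_worked_imbalanced_example(self):
        # cancer (80, 60), normal (20): center = (70 + 20)/2 = 45
        scores, classes = self.frame([80.0, 60.0], [20.0])
        centered = weighted_mean_center(scores, classes, weighted=True)
        assert np.allclose(centered.iloc[0], [35.0, 15.0, -25.0])

    def test_equal_class_sizes_match_plain_centering(self, rng):
        scores, classes = self.frame(rng.normal(size=6), rng.normal(size=6))
        a = weighted_mean_center(scores, classes, weighted=True)
        b = weighted_mean_center(scores, classes, weighted=False)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicating_cancer_samples_leaves_normal_values_fixed(self, rng):
        cancer = list(rng.normal(size=4))
        normal = list(rng.normal(size=3))
        scores1, classes1 = self.frame(cancer, normal)
        scores2, classes2 = self.frame(cancer + cancer, normal)
        c1 = weighted_mean_center(scores1, classes1, weighted=True)
        c2 = weighted_mean_center(scores2, classes2, weighted=True)
        assert np.allclose(
            c1[[f"n{i}" for i in range(3)]], c2[[f"n{i}" for i in range(3)]]
        )

    def test_weighted_requires_both_classes(self):
        scores, classes = self.frame([1.0, 2.0], [])
        with pytest.raises(ValueError, match="both"):
            weighted_mean_center(scores, classes, weighted=True)
        weighted_mean_center(scores, classes, weighted=False)  # plain mean is fine


def cohort(values, cid, n_cancer):
    m = matrix_from(values, cohort_id=cid,
                    sample_ids=[f"{cid}_s{i}" for i in range(np.shape(values)[1])])
    classes = pd.Series(
        ["cancer"] * n_cancer + ["normal"] * (m.n_samples - n_cancer), index=m.sample_ids
    )
    return m, classes


class TestMetaMatrix:
    def test_single_cohort_meta_reduces_to_plain_de(self, rng):
        values = rng.normal(size=(40, 20))
        m, classes = cohort(values, "a", 10)
        mm = sb.build_meta_matrix([(m, classes)])
        meta = sb.meta_de(mm).set_index("gene_id")
        centered = weighted_mean_center(
            pd.DataFrame(rank_normalize(values), index=m.data.index, columns=m.data.columns),
            classes,
        )
        direct = sb.mann_whitney_de(
            sb.ExpressionMatrix(centered, "a"), classes
        ).set_index("gene_id")
        assert np.allclose(meta["p_value"], direct.loc[meta.index, "p_value"])
        assert (meta["direction"] == direct.loc[meta.index, "direction"]).all()

    def test_missing_gene_uses_only_covering_cohorts(self, rng):
        m1, c1 = cohort(rng.normal(size=(5, 12)), "a", 6)
        m2, c2 = cohort(rng.normal(size=(5, 10)), "b", 5)
        m3, c3 = cohort(rng.normal(size=(4, 14)), "c", 7)  # lacks gene g4
        m3 = sb.ExpressionMatrix(m3.data.set_axis(["g0", "g1", "g2", "g3"]), "c")
        mm = sb.build_meta_matrix([(m1, c1), (m2, c2), (m3, c3)])
        assert mm.cohorts_of("g4") == ["a", "b"]
        meta = sb.meta_de(mm).set_index("gene_id")
        # oracle: pool only cohorts a and b for g4
        sub = sb.build_meta_matrix([(m1, c1), (m2, c2)])
        ref = sb.meta_de(sub).set_index("gene_id")
        assert meta.loc["g4", "p_value"] == pytest.approx(ref.loc["g4", "p_value"])

    def test_duplicate_sample_ids_across_cohorts_rejected(self, rng):
        m1, c1 = cohort(rng.normal(size=(4, 8)), "a", 4)
        m2 = sb.ExpressionMatrix(m1.data.copy(), "b")
        with pytest.raises(ValueError, match="cohort"):
            sb.build_meta_matrix([(m1, c1), (m2, c1)])

    def test_pipeline_invariant_under_per_cohort_monotone_transforms(self, rng):
        m1, c1 = cohort(rng.normal(size=(30, 16)), "a", 8)
        m2, c2 = cohort(rng.normal(size=(30, 12)), "b", 6)
        meta1 = sb.meta_de(sb.build_meta_matrix([(m1, c1), (m2, c2)]))
        t1 = sb.ExpressionMatrix(np.exp(m1.data / 3.0), "a")  # strictly increasing
        t2 = sb.ExpressionMatrix(m2.data * 2.5 + 7.0, "b")
        meta2 = sb.meta_de(sb.build_meta_matrix([(t1, c1), (t2, c2)]))
        pd.testing.assert_frame_equal(meta1, meta2)

    def test_null_p_values_are_uniform(self):
        # two cohorts with no planted effects, balanced classes
        cfg = sb.TissueProfileConfig(
            n_genes=2000, n_cancer_samples=25, n_normal_samples=25,
            frac_stroma_up=0, frac_stroma_down=0, frac_cancer_de=0, seed=42,
        )
        pair = sb.generate_suite(cfg, 2, histopathology=[True, True])
        mm = sb.build_meta_matrix(
            [(c.matrix, c.annotation.set_index("sample_id")["class"]) for c in pair]
        )
        meta = sb.meta_de(mm)
        assert kstest(meta["p_value"], "uniform").pvalue > 0.01

    def test_contrast_subset_restricts_samples(self, rng):
        m1, c1 = cohort(rng.normal(size=(10, 20)), "a", 10)
        subset = [s for s in m1.sample_ids if s.endswith(("0", "1", "2"))]
        mm = sb.build_meta_matrix([(m1, c1)])
        meta_full = sb.meta_de(mm)
        meta_sub = sb.meta_de(mm, subset)
        assert not np.allclose(meta_full["p_value"], meta_sub["p_value"])
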