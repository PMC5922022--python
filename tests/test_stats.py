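from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

import stromabalance as sb

from conftest import matrix_from


def enumeration_oracle(x, y):
    """Exhaustive two-sided Mann-Whitney p by enumerating every split of the
    pooled values into groups of the observed sizes (plain-Python)."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2.0

    def u_of(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def de_one_gene(x, y):
    m = matrix_from([list(x) + list(y)])
    classes = {f"s{i}": ("cancer" if i < len(x) else "normal") for i in range(len(x) + len(y))}
    return sb.mann_whitney_de(m, classes).iloc[0]


class TestMannWhitney:
    def test_worked_exact_example(self):
        # cancer entirely above normal in a 2v2 layout: p = 2/C(4,2) = 1/3
        row = de_one_gene([5, 6], [1, 2])
        assert row["p_value"] == pytest.approx(1 / 3)
        assert row["direction"] == "up"

    def test_constant_gene_is_null_up(self):
        row = de_one_gene([3, 3, 3, 3, 3], [3, 3, 3, 3])
        assert row["p_value"] == 1.0
        assert row["direction"] == "up"

    def test_label_swap_flips_direction_keeps_p(self, rng):
        values = rng.normal(size=(30, 20))
        m = matrix_from(values)
        cls = {f"s{i}": ("cancer" if i < 8 else "normal") for i in range(20)}
        swapped = {s: ("normal" if c == "cancer" else "cancer") for s, c in cls.items()}
        a = sb.mann_whitney_de(m, cls).set_index("gene_id")
        b = sb.mann_whitney_de(m, swapped).set_index("gene_id")
        assert np.allclose(a["p_value"], b.loc[a.index, "p_value"])
        flip = {"up": "down", "down": "up"}
        # direction flips except for exactly-tied genes (both report "up")
        ties = a["p_value"] == 1.0
        assert (b.loc[a.index[~ties], "direction"]
                == a.loc[~ties, "direction"].map(flip)).all()

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 4), (4, 4), (3, 7), (5, 5), (2, 8)])
    def test_exact_branch_matches_enumeration_oracle(self, n1, n2, rng):
        for trial in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            if trial == 2:  # force ties across the groups
                x = np.round(x)
                y = np.round(y)
            row = de_one_gene(x, y)
            assert row["p_value"] == pytest.approx(enumeration_oracle(x, y))

    def test_asymptotic_branch_matches_scipy(self, rng):
        values = rng.normal(size=(50, 25))
        values[:10] = np.round(values[:10])  # tied blocks exercise the correction
        m = matrix_from(values)
        cls = {f"s{i}": ("cancer" if i < 12 else "normal") for i in range(25)}
        ours = sb.mann_whitney_de(m, cls).set_index("gene_id")
        ref = mannwhitneyu(
            values[:, :12], values[:, 12:], axis=1, method="asymptotic", use_continuity=False
        ).pvalue
        got = ours.loc[[f"g{i}" for i in range(50)], "p_value"].to_numpy()
        assert np.allclose(got, ref)

    def test_requires_two_samples_per_class(self):
        m = matrix_from(np.zeros((2, 3)))
        cls = {"s0": "cancer", "s1": "normal", "s2": "normal"}
        with pytest.raises(ValueError, match=">= 2"):
            sb.mann_whitney_de(m, cls)

    def test_ranks_are_permutation_and_q_bounds_p(self, small_cohort):
        de = sb.mann_whitney_de(
            small_cohort.matrix, small_cohort.annotation.set_index("sample_id")["class"]
        )
        assert sorted(de["rank"]) == list(range(1, len(de) + 1))
        assert (de["q_value"] >= de["p_value"] - 1e-15).all()
        assert (de["q_value"] <= 1.0).all()


class TestBHFDR:
    def test_hand_applied_step_up(self):
        q = sb.bh_fdr([0.01, 0.02, 0.03], 3)
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert sb.bh_fdr([0.01], 1)[0] == pytest.approx(0.01)

    def test_global_gene_count_scaling(self):
        # correcting a lone p-value at the full cross-cohort universe
        assert sb.bh_fdr([1e-6], 25964)[0] == pytest.approx(0.025964)

    def test_matches_statsmodels_when_m_equals_n(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        ours = sb.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = sb.bh_fdr(p, 500)
        bumped = p.copy()
        i = int(rng.integers(0, 100))
        bumped[i] = min(1.0, bumped[i] + 0.1)
        q2 = sb.bh_fdr(bumped, 500)
        assert (q2 >= q - 1e-12).all()

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            sb.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            sb.bh_fdr([0.1, 0.2], 1)


class TestCollapseProbes:
    def probe_matrix(self):
        return matrix_from(
            [[1.0, 2.0], [5.0, 9.0], [3.0, 3.0]], ["p1", "p2", "p3"], ["s1", "s2"]
        )

    def test_single_probe_gene_kept_under_every_strategy(self):
        m = self.probe_matrix()
        mapping = {"p1": "gA", "p2": "gB", "p3": "gC"}
        ranks = [{"p1": 5, "p2": 1, "p3": 3}]
        for strategy, ctx in [("max_expression", None), ("best_de_rank", ranks),
                              ("best_avg_de_rank", ranks)]:
            out = sb.collapse_probes(m, mapping, strategy, ctx)
            assert sorted(out.gene_ids) == ["gA", "gB", "gC"]

    def test_best_average_rank_selects_smallest_mean(self):
        m = matrix_from(np.zeros((2, 2)), ["pA", "pB"])
        mapping = {"pA": "g", "pB": "g"}
        ctx = [{"pA": 10, "pB": 100}, {"pA": 500, "pB": 110}, {"pA": 20, "pB": 120}]
        out = sb.collapse_probes(m, mapping, "best_avg_de_rank", ctx)
        # means: pA = 176.7, pB = 110 -> pB wins
        assert out.data.index.tolist() == ["g"]
        assert (out.data.loc["g"] == m.data.loc["pB"]).all()

    def test_max_expression_keeps_brightest_probe(self):
        m = matrix_from([[3.0, 3.0], [7.0, 7.0]], ["p1", "p2"])
        out = sb.collapse_probes(m, {"p1": "g", "p2": "g"}, "max_expression")
        assert (out.data.loc["g"] == 7.0).all()

    def test_unmapped_probes_dropped_and_empty_mapping_errors(self):
        m = self.probe_matrix()
        out = sb.collapse_probes(m, {"p1": "gA"}, "max_expression")
        assert out.gene_ids == ["gA"]
        with pytest.raises(ValueError):
            sb.collapse_probes(m, {}, "max_expression")
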