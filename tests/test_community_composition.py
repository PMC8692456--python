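"""Rarefaction, diversity, compositional transforms, ANOSIM/SIMPER."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from leucarb.community_composition import (
    ASVTable,
    aggregate_phylotypes,
    anosim,
    bray_curtis,
    clr,
    diversity,
    fit_clr_vs_cf,
    rarefy,
    remove_singletons,
    simper,
    zero_replace,
    zero_replace_clr,
)
from leucarb.synthetic_data import CommunitySimParams, simulate_asv_table


class TestRarefy:
    def test_row_sums_equal_depth(self, small_asv_table):
        out = rarefy(small_asv_table, 300, seed=1)
        assert (out.counts.sum(axis=1) == 300).all()

    def test_sample_at_depth_unchanged(self, small_asv_table):
        total = int(small_asv_table.counts.iloc[0].sum())
        out = rarefy(small_asv_table, total, seed=1)
        assert (out.counts.iloc[0] == small_asv_table.counts.iloc[0]).all()

    def test_deterministic_under_seed(self, small_asv_table):
        a = rarefy(small_asv_table, 300, seed=9)
        b = rarefy(small_asv_table, 300, seed=9)
        assert a.counts.equals(b.counts)

    def test_no_new_taxa(self, small_asv_table):
        out = rarefy(small_asv_table, 300, seed=2)
        assert ((small_asv_table.counts == 0) >= (out.counts == 0)).values.all() or \
            ((out.counts[small_asv_table.counts == 0] == 0).fillna(True)).values.all()

    def test_below_depth_rejected_by_name(self, small_asv_table):
        with pytest.raises(ValueError, match="s0"):
            rarefy(small_asv_table, 10_000)

    def test_expected_proportion_preserved(self, small_asv_table):
        # hypergeometric mean: expected subsampled proportion = input proportion
        p_in = (small_asv_table.counts.iloc[0]
                / small_asv_table.counts.iloc[0].sum())
        draws = [
            rarefy(small_asv_table, 200, seed=s).counts.iloc[0] / 200
            for s in range(100)
        ]
        p_out = pd.concat(draws, axis=1).mean(axis=1)
        se = np.sqrt(p_in * (1 - p_in) / (200 * 100))
        dominant = p_in.idxmax()
        assert abs(p_out[dominant] - p_in[dominant]) < 3 * se[dominant] + 1e-12


class TestDiversity:
    def test_single_asv_zero_entropy(self):
        assert diversity([100]).shannon_h == 0.0

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_equal_abundances_ln_k(self, k):
        assert diversity([50] * k).shannon_h == pytest.approx(math.log(k))

    def test_chao1_no_singletons_equals_observed(self):
        m = diversity([5, 10, 3, 2])
        assert m.chao1 == m.observed_asvs == 4

    def test_chao1_bias_corrected_formula(self):
        # F1=2, F2=1 -> chao1 = 4 + 2*1/(2*2) = 4.5
        m = diversity([1, 1, 2, 7])
        assert m.chao1 == pytest.approx(4.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity([0, 0])


class TestAggregatePhylotypes:
    def test_all_abundant_identity(self, small_asv_table):
        out = aggregate_phylotypes(small_asv_table, threshold=0.0)
        assert out.shape == small_asv_table.counts.shape

    def test_column_sums_conserved(self, small_asv_table):
        out = aggregate_phylotypes(small_asv_table, threshold=0.05)
        assert out.to_numpy().sum() == small_asv_table.counts.to_numpy().sum()
        assert (out.sum(axis=1) == small_asv_table.counts.sum(axis=1)).all()

    def test_rare_asvs_pool_into_others(self):
        counts = pd.DataFrame(
            {"A": [970, 970], "B": [4, 4], "C": [4, 4], "D1": [8, 8], "D2": [8, 8]},
            index=["s1", "s2"],
        )
        taxonomy = pd.Series(["P1", "P2", "P3", "P4", "P4"],
                             index=["A", "B", "C", "D1", "D2"])
        table = ASVTable(counts, taxonomy)
        out = aggregate_phylotypes(table, threshold=0.01)
        # B, C rare and alone in their phyla -> Others; D1+D2 reach 1% as P4
        assert "A" in out.columns and "Others" in out.columns
        assert out["Others"].sum() == 16  # B + C pooled
        assert "P4" in out.columns
        assert out["P4"].sum() == 32


class TestANOSIM:
    def test_bray_curtis_range_and_diagonal(self, small_asv_table):
        d = bray_curtis(small_asv_table.counts)
        assert ((d.values >= 0) & (d.values <= 1)).all()
        assert np.allclose(np.diag(d.values), 0)

    def test_disjoint_compositions_r_one(self):
        counts = pd.DataFrame(
            [[10, 0, 5, 0], [8, 0, 7, 0], [0, 10, 0, 5], [0, 7, 0, 9]],
            index=list("abcd"), columns=["x1", "x2", "x3", "x4"],
        )
        res = anosim(bray_curtis(counts), ["g1", "g1", "g2", "g2"],
                     n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_homogeneous_cloud_null(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.multinomial(500, [0.25] * 4, size=8))
        res = anosim(bray_curtis(counts), ["a"] * 4 + ["b"] * 4,
                     n_permutations=199, seed=1)
        assert abs(res.r) < 0.3
        assert res.p_value > 0.1

    def test_six_sample_exhaustive_permutation_oracle(self, small_asv_table):
        """R matches an independent rank implementation and the permutation
        p-value matches exhaustive enumeration of all 720 orderings."""
        agg = small_asv_table.counts
        labels = np.array(["epi"] * 3 + ["bathy"] * 3)
        d = bray_curtis(agg)
        res = anosim(d, labels, n_permutations=719, seed=3)

        def oracle_r(dist, labs):
            pairs, kinds = [], []
            for i in range(6):
                for j in range(i + 1, 6):
                    pairs.append(dist.iloc[i, j])
                    kinds.append(labs[i] == labs[j])
            order = np.argsort(pairs, kind="stable")
            ranks = np.empty(len(pairs))
            # average ranks for ties, built by hand
            sorted_vals = np.array(pairs)[order]
            k = 0
            while k < len(pairs):
                m = k
                while m + 1 < len(pairs) and sorted_vals[m + 1] == sorted_vals[k]:
                    m += 1
                for t in range(k, m + 1):
                    ranks[order[t]] = (k + m) / 2 + 1
                k = m + 1
            kinds = np.array(kinds)
            rw = ranks[kinds].mean()
            rb = ranks[~kinds].mean()
            return (rb - rw) / (len(pairs) / 2)

        assert res.r == pytest.approx(oracle_r(d, labels), rel=1e-12)

        r_obs = oracle_r(d, labels)
        hits = sum(
            oracle_r(d, np.array(perm)) >= r_obs - 1e-12
            for perm in itertools.permutations(labels)
        )
        exact_p = hits / math.factorial(6)
        assert res.p_value == pytest.approx(exact_p, abs=0.05)

    def test_r_matches_skbio(self, small_asv_table):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        d = bray_curtis(small_asv_table.counts)
        labels = ["epi"] * 3 + ["bathy"] * 3
        res = anosim(d, labels, n_permutations=99, seed=0)
        ref = skbio_stats.anosim(
            DistanceMatrix(d.values, ids=list(d.index)), labels, permutations=0,
        )
        assert res.r == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_singleton_group_rejected(self, small_asv_table):
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(bray_curtis(small_asv_table.counts),
                   ["a", "b", "b", "b", "b", "b"])


class TestSIMPER:
    def test_pair_contributions_sum_to_bray_curtis(self, small_asv_table):
        counts = small_asv_table.counts
        labels = ["epi"] * 3 + ["bathy"] * 3
        out = simper(counts, labels)
        table = out[("bathy", "epi")] if ("bathy", "epi") in out else out[("epi", "bathy")]
        d = bray_curtis(counts)
        mean_bc = np.mean([d.iloc[i, j] for i in range(3) for j in range(3, 6)])
        assert table["mean_contribution"].sum() == pytest.approx(mean_bc, abs=1e-9)
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_discriminating_taxon_ranks_first(self, small_asv_table):
        labels = ["epi"] * 3 + ["bathy"] * 3
        out = simper(small_asv_table.counts, labels)
        top = next(iter(out.values())).index[0]
        # the most surface- or deep-skewed ASVs drive the dissimilarity
        assert top in {"ASV0", "ASV6", "ASV7"}


class TestCompositional:
    def test_zero_free_equal_counts_clr_zero(self):
        counts = pd.DataFrame([[5, 5, 5, 5]], index=["s"], columns=list("abcd"))
        out = clr(zero_replace(counts))
        assert np.allclose(out.values, 0.0)

    def test_clr_rows_sum_to_zero(self, small_asv_table):
        out = zero_replace_clr(small_asv_table)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_replaced_zeros_positive_ranking_preserved(self):
        rng = np.random.default_rng(17)
        probs = [0.45, 0.25, 0.15, 0.07, 0.05, 0.03, 0.0, 0.0]
        counts = pd.DataFrame(rng.multinomial(200, probs, size=5))
        repl = zero_replace(counts)
        assert (repl.values > 0).all()
        assert np.allclose(repl.sum(axis=1), 1.0)
        for i in range(len(counts)):
            row = counts.iloc[i]
            nz = row[row > 0].sort_values().index
            vals = repl.iloc[i][nz].to_numpy()
            assert (np.diff(vals) >= -1e-15).all()

    def test_clr_scale_invariance(self):
        props = pd.DataFrame([[0.5, 0.3, 0.2]], index=["s"], columns=list("abc"))
        assert np.allclose(clr(props).values, clr(props * 7.3).values)

    def test_clr_matches_skbio(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        props = pd.DataFrame([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3]], columns=list("abc"))
        assert np.allclose(clr(props).values, skbio_comp.clr(props.values))

    def test_all_zero_row_rejected(self):
        counts = pd.DataFrame([[0, 0, 0]], index=["s"], columns=list("abc"))
        with pytest.raises(ValueError, match="s"):
            zero_replace(counts)


class TestCLRvsCF:
    def test_exact_quadratic_selected_and_recovered(self):
        ecf = np.array([0.2, 1.0, 2.0, 3.0, 4.0])
        y = 0.8 * ecf**2 - 3.0 * ecf + 1.0
        fit = fit_clr_vs_cf(y, ecf, "Actinomarina_1")
        assert fit.model == "quadratic"
        assert np.allclose(fit.coefficients, (0.8, -3.0, 1.0), atol=1e-9)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_selects_linear(self):
        ecf = np.array([0.2, 1.0, 2.0, 3.0, 4.0])
        fit = fit_clr_vs_cf(2.0 * ecf - 1.0, ecf)
        assert fit.model == "linear"

    def test_selection_equals_aic_oracle(self):
        rng = np.random.default_rng(2)
        ecf = np.array([0.2, 0.9, 1.7, 2.5, 3.3, 4.0])
        y = -(ecf - 2) ** 2 + rng.normal(0, 0.4, 6)
        fit = fit_clr_vs_cf(y, ecf)
        assert fit.model == ("quadratic" if fit.quadratic_aic < fit.linear_aic
                             else "linear")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_clr_vs_cf([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_remove_singletons_drops_single_count_asvs():
    counts = pd.DataFrame({"A": [3, 4], "B": [1, 0], "C": [0, 1], "D": [2, 0]},
                          index=["s1", "s2"])
    taxonomy = pd.Series(["P"] * 4, index=list("ABCD"))
    out = remove_singletons(ASVTable(counts, taxonomy))
    assert list(out.counts.columns) == ["A", "D"]
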