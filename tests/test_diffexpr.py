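"""Normalization, dispersion, Wald test, and DEG-combination contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modnet_germ import diffexpr as dx
from modnet_germ.io_formats import DegenerateInputError
from modnet_germ.synthetic import plant_truth, simulate_counts

from conftest import toy_matrix


def brute_force_bh(p):
    """Independent step-up reference: adj_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBH:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.max(np.abs(dx.bh_adjust(p) - brute_force_bh(p))) < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        ours = dx.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(ours - theirs)) < 1e-12

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adj = dx.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = toy_matrix([[10, 10], [5, 5], [100, 100]])
        sf = dx.size_factors(cm)
        assert np.allclose(sf.s, 1.0)

    def test_doubled_column(self):
        cm = toy_matrix([[10, 20], [100, 200], [4, 8]])
        sf = dx.size_factors(cm)
        assert np.allclose(sf.s.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(40, 6))
        cm = toy_matrix(counts, lines=("A", "B", "C"), replicates=2)
        sf = dx.size_factors(cm)
        cm2 = toy_matrix(counts[rng.permutation(40)], lines=("A", "B", "C"), replicates=2)
        assert np.allclose(sf.s.values, dx.size_factors(cm2).s.values)

    def test_column_scaling_scales_factor(self):
        counts = np.array([[10, 20], [100, 200], [4, 8]])
        scaled = counts.copy()
        scaled[:, 1] *= 3
        s1 = dx.size_factors(toy_matrix(counts)).s
        s2 = dx.size_factors(toy_matrix(scaled)).s
        # geometric means rescale too, so the exact invariance is on the
        # ratio of factors between samples: it triples exactly
        assert (s2.iloc[1] / s2.iloc[0]) / (s1.iloc[1] / s1.iloc[0]) == pytest.approx(3.0)

    def test_fallback_used_when_no_all_positive_gene(self):
        cm = toy_matrix([[0, 10], [10, 0]])
        with pytest.raises(DegenerateInputError):
            dx.size_factors(cm, allow_fallback=False)
        sf = dx.size_factors(cm, allow_fallback=True)
        assert (sf.s > 0).all()


class TestVST:
    def _fixtures(self, alpha):
        cm = toy_matrix([[0, 48], [100, 100], [7, 7]])
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.DispersionEstimate(
            per_gene=pd.Series(alpha, index=cm.counts.index), common=alpha
        )
        return cm, sf, disp

    def test_zero_maps_to_zero(self):
        cm, sf, disp = self._fixtures(0.25)
        v = dx.vst(cm, sf, disp)
        assert v.iloc[0, 0] == 0.0

    def test_small_alpha_limit_is_two_sqrt(self):
        cm, sf, disp = self._fixtures(1e-10)
        v = dx.vst(cm, sf, disp)
        assert v.loc["g1"].iloc[0] == pytest.approx(2 * np.sqrt(100), rel=1e-5)

    def test_closed_form(self):
        cm, sf, disp = self._fixtures(0.25)
        v = dx.vst(cm, sf, disp)
        expected = (2 / np.sqrt(0.25)) * np.arcsinh(np.sqrt(0.25 * 48))
        assert v.loc["g0"].iloc[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4 * np.arcsinh(np.sqrt(12)))

    def test_strictly_increasing(self):
        cm, sf, disp = self._fixtures(0.1)
        q = np.linspace(0, 50, 100)
        v = (2 / np.sqrt(0.1)) * np.arcsinh(np.sqrt(0.1 * q))
        assert (np.diff(v) > 0).all()

    def test_nonpositive_alpha_rejected(self):
        cm, sf, _ = self._fixtures(0.1)
        disp = dx.DispersionEstimate(
            per_gene=pd.Series(0.0, index=cm.counts.index), common=0.0
        )
        with pytest.raises(ValueError):
            dx.vst(cm, sf, disp)


class TestDispersion:
    def test_constant_counts_floor(self):
        cm = toy_matrix([[5, 5, 7, 7], [9, 9, 2, 2]], lines=("A", "B"), replicates=2)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.estimate_dispersion(cm, sf)
        assert (disp.per_gene == dx.ALPHA_MIN).all()

    def test_poisson_counts_near_floor(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(200, 500))
        cm = toy_matrix(counts, lines=("A",), replicates=500)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.estimate_dispersion(cm, sf)
        assert disp.common < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        alpha, mu = 0.2, 200.0
        lam = rng.gamma(1 / alpha, alpha * mu, size=(200, 200))
        counts = rng.poisson(lam)
        cm = toy_matrix(counts, lines=("A",), replicates=200)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.estimate_dispersion(cm, sf)
        assert 0.1 <= disp.common <= 0.3

    def test_requires_replicates(self):
        cm = toy_matrix([[1, 2], [3, 4]])
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        with pytest.raises(DegenerateInputError):
            dx.estimate_dispersion(cm, sf)


class TestWald:
    def _cm(self, a, b):
        counts = np.column_stack([a, b]).reshape(len(a), -1)
        counts = np.hstack([np.asarray(a), np.asarray(b)]).reshape(1, -1)
        return counts

    def test_identical_groups_null(self):
        counts = np.array([[10, 20, 30, 10, 20, 30], [5, 5, 5, 5, 5, 5]])
        cm = toy_matrix(counts, lines=("Llpa", "LWT"), replicates=3)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.DispersionEstimate(
            per_gene=pd.Series(0.01, index=cm.counts.index), common=0.01
        )
        rec = dx.nb_wald_test(cm, sf, disp, ("Llpa", "LWT"), 1)
        assert rec["lfc"].abs().max() == 0.0
        assert (rec["p"] == 1.0).all()

    def test_closed_form_values(self):
        # group means 30 vs 10, n = 3 each, alpha = 0.01
        counts = np.array([[20, 30, 40, 5, 10, 15]])
        cm = toy_matrix(counts, lines=("Llpa", "LWT"), replicates=3)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.DispersionEstimate(
            per_gene=pd.Series(0.01, index=cm.counts.index), common=0.01
        )
        rec = dx.nb_wald_test(cm, sf, disp, ("Llpa", "LWT"), 1)
        lfc = np.log2(31 / 11)
        se = np.sqrt((1 / 3) * (1 / 31 + 0.01) + (1 / 3) * (1 / 11 + 0.01)) / np.log(2)
        z = lfc / se
        assert rec["lfc"].iloc[0] == pytest.approx(lfc, rel=1e-12)
        assert rec["se"].iloc[0] == pytest.approx(se, rel=1e-12)
        assert rec["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)
        assert rec["baseMean"].iloc[0] == pytest.approx(20.0)

    def test_missing_stage_rejected(self):
        cm = toy_matrix([[1, 2, 3, 4, 5, 6]], lines=("Llpa", "LWT"), replicates=3)
        sf = dx.SizeFactors(s=pd.Series(1.0, index=cm.counts.columns))
        disp = dx.DispersionEstimate(
            per_gene=pd.Series(0.01, index=cm.counts.index), common=0.01
        )
        with pytest.raises(ValueError, match="stage"):
            dx.nb_wald_test(cm, sf, disp, ("Llpa", "LWT"), 3)

    def test_type_one_error_controlled_on_null_data(self):
        # no planted DE, no edges: p < 0.05 fraction stays near nominal
        # under the full design, whose 24 replicate cells give the pooled
        # method-of-moments dispersion stable degrees of freedom
        from modnet_germ.synthetic import generate_design

        design = generate_design("paper_full")
        truth = plant_truth(
            design, n_genes=2000, n_tfs=10, n_modules=4, n_edges=0,
            sigma=0.0, alpha=0.02, seed=71, de_genes_per_cell=0,
            background_frac=0.99,
        )
        cm, _ = simulate_counts(design, truth, seed=72)
        sf = dx.size_factors(cm)
        disp = dx.estimate_dispersion(cm, sf)
        nulls = list(truth.background_genes)
        for comparison in design.comparisons("Mips") + design.comparisons("MipsMRP"):
            for stage in (1, 2, 3):
                rec = dx.nb_wald_test(cm, sf, disp, comparison, stage)
                assert (rec.loc[nulls, "p"] < 0.05).mean() <= 0.07


class TestDegCombination:
    def _rec(self, comparison, stage, deg_genes, universe=("a", "b", "c", "d", "e")):
        df = pd.DataFrame(
            {"is_deg": [g in deg_genes for g in universe]}, index=list(universe)
        )
        df.attrs["comparison"] = comparison
        df.attrs["stage"] = stage
        return df

    def test_mrp_intersection_rule(self):
        recs = [
            self._rec(("2mlpa", "2MWT"), 1, {"a", "b"}),
            self._rec(("2mlpa", "2MWT-L"), 1, {"a", "b", "c"}),
            self._rec(("2mlpa", "2MWT-N"), 1, {"a", "c"}),
        ]
        out = dx.call_degs_subset(recs, "MRP")
        assert out[1] == {"a"}

    def test_mrp_two_of_three_excluded(self):
        recs = [
            self._rec(("2mlpa", "2MWT"), 1, {"b"}),
            self._rec(("2mlpa", "2MWT-L"), 1, {"b"}),
            self._rec(("2mlpa", "2MWT-N"), 1, set()),
        ]
        assert dx.call_degs_subset(recs, "MRP")[1] == set()

    def test_single_comparison_identity(self):
        recs = [self._rec(("1mlpa", "1MWT"), 1, {"a", "c", "d", "e", "b"})]
        assert dx.call_degs_subset(recs, "Mips")[1] == {"a", "b", "c", "d", "e"}

    def test_wrong_comparison_count_rejected(self):
        recs = [self._rec(("2mlpa", "2MWT"), 1, {"a"})]
        with pytest.raises(ValueError, match="3 comparison"):
            dx.call_degs_subset(recs, "MRP")


class TestVenn:
    def test_brute_force_example(self):
        regions = dx.venn_partition({1: {"a", "b"}, 2: {"b", "c"}, 3: {"c"}})
        assert regions == {
            "only_1": 1, "only_2": 0, "only_3": 0,
            "s1_s2": 1, "s2_s3": 1, "s1_s3": 0, "all": 0,
        }

    def test_identical_sets(self):
        s = {"x", "y", "z"}
        regions = dx.venn_partition({1: set(s), 2: set(s), 3: set(s)})
        assert regions["all"] == 3
        assert sum(v for k, v in regions.items() if k != "all") == 0

    def test_empty_sets(self):
        regions = dx.venn_partition({1: set(), 2: set(), 3: set()})
        assert all(v == 0 for v in regions.values())

    def test_regions_sum_to_union(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sets = {
                s: set(rng.choice(50, size=rng.integers(0, 30), replace=False))
                for s in (1, 2, 3)
            }
            regions = dx.venn_partition(sets)
            assert sum(regions.values()) == len(sets[1] | sets[2] | sets[3])
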