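"""Correctness of the five edge scorers, binarization, and the vote."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from modnet_germ import grn
from modnet_germ.io_formats import METHOD_ORDER


def gaussian_chain(n, rho_xy, rho_yz, seed):
    """X -> Y -> Z Markov chain with the given link correlations."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rho_xy * x + np.sqrt(1 - rho_xy**2) * rng.normal(size=n)
    z = rho_yz * y + np.sqrt(1 - rho_yz**2) * rng.normal(size=n)
    return x, y, z


def random_matrix(n=12, n_tf=5, n_mod=3, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"TF{i}" for i in range(n_tf)] + [f"M{j+1}" for j in range(n_mod)]
    return (
        pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols),
        cols[:n_tf],
        cols[n_tf:],
    )


class TestGaussianMI:
    def test_closed_form_from_spearman(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        rho_s = spearmanr(x, y).statistic
        rho = np.clip(2 * np.sin(np.pi * rho_s / 6), -0.9999, 0.9999)
        assert grn.gaussian_mi(x, y) == pytest.approx(-0.5 * np.log(1 - rho**2), rel=1e-9)

    def test_identical_vectors_hit_cap(self):
        x = np.arange(10.0)
        expected = -0.5 * np.log(1 - 0.9999**2)
        assert grn.gaussian_mi(x, x) == pytest.approx(expected, rel=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = rng.permutation(x)
        assert grn.gaussian_mi(x, y) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            grn.gaussian_mi(np.ones(10), np.arange(10.0))

    def test_monotone_in_association(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        mis = []
        for rho in (0.2, 0.5, 0.8, 0.95):
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=300)
            mis.append(grn.gaussian_mi(x, y))
        assert (np.diff(mis) > 0).all()


class TestAracne:
    def test_chain_prunes_indirect_edge(self):
        x, y, z = gaussian_chain(500, 0.9, 0.9, seed=3)
        mat = pd.DataFrame({"TFx": x, "M1": y, "M2": z})
        scores = grn.aracne_scores(mat, ["TFx"], ["M1", "M2"], tolerance=0.0)
        assert scores.at["TFx", "M1"] > 0  # direct
        assert scores.at["TFx", "M2"] == 0  # indirect, pruned

    def test_indirect_edge_pruned_even_with_tolerance(self):
        # at rho = 0.8 the DPI margin is wide enough that the indirect edge
        # falls below (1 - 0.3) * min(direct MIs) with room to spare
        x, y, z = gaussian_chain(500, 0.8, 0.8, seed=3)
        mat = pd.DataFrame({"TFx": x, "M1": y, "M2": z})
        loose = grn.aracne_scores(mat, ["TFx"], ["M1", "M2"], tolerance=0.3)
        assert loose.at["TFx", "M2"] == 0
        assert loose.at["TFx", "M1"] > 0

    def test_equal_mi_triangle_keeps_all_edges(self):
        mi = pd.DataFrame(0.5, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(mi.to_numpy(), 0.0)
        pruned = grn.dpi_prune(mi, tolerance=0.0)
        off = pruned.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 0.5).all()


class TestCLR:
    def test_constant_mi_gives_zero(self):
        mi = pd.DataFrame(0.3, index=["a", "b"], columns=["m", "n"])
        assert (grn.clr_from_mi(mi).to_numpy() == 0).all()

    def test_dominant_pair_has_largest_score(self):
        rng = np.random.default_rng(4)
        mi = pd.DataFrame(
            rng.uniform(0, 0.1, size=(6, 5)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"m{j}" for j in range(5)],
        )
        mi.at["t2", "m3"] = 2.0
        scores = grn.clr_from_mi(mi)
        assert scores.at["t2", "m3"] == scores.to_numpy().max()

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        mi = pd.DataFrame(rng.uniform(size=(4, 4)))
        a = grn.clr_from_mi(mi)
        b = grn.clr_from_mi(mi + 7.0)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestLars:
    def test_perfect_predictor_scores_one(self):
        mat, tfs, mods = random_matrix(seed=6)
        mat["M1"] = 2.0 * mat["TF3"]
        scores = grn.lars_scores(mat, tfs, mods, max_steps=3)
        assert scores.at["TF3", "M1"] == 1.0

    def test_first_entry_is_max_correlation(self):
        mat, tfs, mods = random_matrix(n=30, seed=7)
        scores = grn.lars_scores(mat, tfs, mods, max_steps=1)
        X = mat[tfs].to_numpy()
        X = (X - X.mean(0)) / X.std(0)
        for mod in mods:
            y = mat[mod] - mat[mod].mean()
            best = tfs[int(np.argmax(np.abs(X.T @ y)))]
            assert scores.at[best, mod] == 1.0

    def test_never_entered_scores_zero(self):
        mat, tfs, mods = random_matrix(seed=8)
        scores = grn.lars_scores(mat, tfs, mods, max_steps=2)
        assert ((scores > 0).sum(axis=0) <= 2).all()

    def test_max_steps_bounded_by_conditions(self):
        mat, tfs, mods = random_matrix(n=5, seed=9)
        with pytest.raises(ValueError, match="max_steps"):
            grn.lars_scores(mat, tfs, mods, max_steps=5)


class TestPcor:
    def test_lambda_one_zeroes_everything(self):
        mat, tfs, mods = random_matrix(seed=10)
        scores = grn.pcor_scores(mat, tfs, mods, "fixed", 1.0)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(
            {"TF0": rng.normal(size=30)}
        )
        mat["M1"] = 0.8 * mat["TF0"] + 0.3 * rng.normal(size=30)
        lam = 0.2
        scores = grn.pcor_scores(mat, ["TF0"], ["M1"], "fixed", lam)
        r = np.corrcoef(mat["TF0"], mat["M1"])[0, 1]
        assert scores.at["TF0", "M1"] == pytest.approx(abs((1 - lam) * r), rel=1e-9)

    def test_chain_conditional_independence(self):
        x, y, z = gaussian_chain(500, 0.9, 0.9, seed=12)
        mat = pd.DataFrame({"TFx": x, "M1": y, "M2": z})
        scores = grn.pcor_scores(mat, ["TFx"], ["M1", "M2"], "fixed", 0.05)
        assert scores.at["TFx", "M2"] < scores.at["TFx", "M1"]

    def test_analytic_lambda_in_bounds(self):
        mat, tfs, mods = random_matrix(n=10, n_tf=20, n_mod=5, seed=13)
        lam = grn._analytic_lambda(mat.to_numpy())
        assert 0.01 <= lam <= 1.0


class TestRF:
    def test_noiseless_function_of_one_tf_dominates(self):
        # impurity importance with sqrt-feature subsampling and bootstrap
        # spreads some credit to noise features even on noiseless targets,
        # so the check is dominance: the driver takes the largest share by
        # a wide margin
        rng = np.random.default_rng(14)
        mat = pd.DataFrame(
            rng.normal(size=(30, 6)), columns=[f"TF{i}" for i in range(6)]
        )
        mat["M1"] = np.sin(mat["TF2"]) + mat["TF2"]
        scores = grn.rf_scores(mat, [f"TF{i}" for i in range(6)], ["M1"], trees=300, seed=1)
        ranked = scores["M1"].sort_values(ascending=False)
        assert ranked.index[0] == "TF2"
        assert ranked.iloc[0] > 0.4
        assert ranked.iloc[0] > 2 * ranked.iloc[1]

    def test_importances_sum_to_one(self):
        mat, tfs, mods = random_matrix(n=30, seed=15)
        scores = grn.rf_scores(mat, tfs, mods, trees=200, seed=2)
        assert np.allclose(scores.sum(axis=0), 1.0, atol=1e-9)

    def test_pure_noise_no_dominant_regulator(self):
        rng = np.random.default_rng(16)
        maxima = []
        for s in range(10):
            mat = pd.DataFrame(
                rng.normal(size=(30, 9)),
                columns=[f"TF{i}" for i in range(8)] + ["M1"],
            )
            scores = grn.rf_scores(mat, [f"TF{i}" for i in range(8)], ["M1"], trees=300, seed=s)
            maxima.append(scores["M1"].max())
        assert max(maxima) < 0.5

    def test_deterministic_given_seed(self):
        mat, tfs, mods = random_matrix(n=20, seed=17)
        a = grn.rf_scores(mat, tfs, mods, trees=100, seed=9)
        b = grn.rf_scores(mat, tfs, mods, trees=100, seed=9)
        assert a.equals(b)


class TestBinarize:
    def _frame(self, entries):
        tfs = sorted({t for t, _, _ in entries})
        mods = sorted({m for _, m, _ in entries})
        df = pd.DataFrame(0.0, index=tfs, columns=mods)
        for t, m, s in entries:
            df.at[t, m] = s
        return df

    def test_top_e_by_score(self):
        df = self._frame([("a", "m1", 5.0), ("b", "m1", 5.0), ("c", "m1", 1.0)])
        assert grn.binarize(df, 2) == {("a", "m1"), ("b", "m1")}

    def test_boundary_tie_lexicographic(self):
        df = self._frame([("a", "m1", 5.0), ("b", "m1", 3.0), ("c", "m1", 3.0)])
        assert grn.binarize(df, 2) == {("a", "m1"), ("b", "m1")}

    def test_zero_scores_never_kept(self):
        df = self._frame([("a", "m1", 0.0), ("b", "m1", 0.0)])
        assert grn.binarize(df, 5) == set()


class TestConsensus:
    def _sets(self, **kwargs):
        base = {m: set() for m in METHOD_ORDER}
        base.update(kwargs)
        return base

    def test_four_method_edge_retained(self):
        e = ("tfA", "m1")
        sets = self._sets(aracne={e}, clr={e}, lars={e}, rf={e})
        out = grn.consensus(sets, kmin=4)
        assert len(out) == 1
        assert out[0].support == 4
        assert out[0].methods == frozenset({"aracne", "clr", "lars", "rf"})

    def test_three_method_edge_dropped(self):
        e = ("tfA", "m1")
        out = grn.consensus(self._sets(aracne={e}, clr={e}, rf={e}), kmin=4)
        assert out == []

    def test_kmin_one_is_union(self):
        sets = self._sets(
            aracne={("a", "m")}, clr={("b", "m")}, lars={("c", "m")},
            pcor={("d", "m")}, rf={("a", "m")},
        )
        out = grn.consensus(sets, kmin=1)
        assert {(e.tf, e.module) for e in out} == {
            ("a", "m"), ("b", "m"), ("c", "m"), ("d", "m")
        }

    def test_monotone_in_kmin(self):
        rng = np.random.default_rng(18)
        universe = [(f"t{i}", f"m{j}") for i in range(6) for j in range(4)]
        sets = {
            m: {universe[i] for i in rng.choice(len(universe), 10, replace=False)}
            for m in METHOD_ORDER
        }
        sizes = [len(grn.consensus(sets, kmin=k)) for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_requires_all_five_methods(self):
        with pytest.raises(ValueError):
            grn.consensus({"aracne": set()}, kmin=1)


class TestRowPermutationInvariance:
    """Scorers depend on the set of conditions, not their order.

    The forest scorer is excluded: its bootstrap resampling is tied to the
    random state, so row permutation changes the draws even at a fixed
    seed (the scores are exchangeable in distribution, not pointwise).
    """

    @pytest.mark.parametrize(
        "scorer",
        [
            lambda m, t, c: grn.aracne_scores(m, t, c, 0.1),
            lambda m, t, c: grn.clr_scores(m, t, c),
            lambda m, t, c: grn.lars_scores(m, t, c, 3),
            lambda m, t, c: grn.pcor_scores(m, t, c, "fixed", 0.1),
        ],
        ids=["aracne", "clr", "lars", "pcor"],
    )
    def test_invariant(self, scorer):
        mat, tfs, mods = random_matrix(n=14, seed=19)
        rng = np.random.default_rng(20)
        permuted = mat.iloc[rng.permutation(len(mat))].reset_index(drop=True)
        a = scorer(mat, tfs, mods)
        b = scorer(permuted, tfs, mods)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)


class TestRegulatorMatrix:
    def test_shape_and_column_order(self, standard_instance):
        import modnet_germ.clustering as cl
        import modnet_germ.diffexpr as dx

        design, truth, cm = standard_instance
        sf = dx.size_factors(cm)
        disp = dx.estimate_dispersion(cm, sf)
        v = dx.vst(cm, sf, disp)
        genes = sorted(truth.module_of)
        prof = cl.build_profiles(v, cm.samples, genes, "MRP")
        means = pd.DataFrame(
            {
                f"M{m}": prof.loc[truth.module_genes(m)].mean(axis=0)
                for m in range(1, truth.n_modules + 1)
            }
        ).T
        tfs = sorted(truth.tf_set)
        mat, tf_cols, mod_cols = grn.build_regulator_matrix(v, cm.samples, tfs, means, "MRP")
        assert mat.shape == (12, len(tfs) + truth.n_modules)
        assert tf_cols == tfs
        assert mod_cols == [f"M{m}" for m in range(1, truth.n_modules + 1)]
        # deterministic: repeated call gives the identical frame
        mat2, _, _ = grn.build_regulator_matrix(v, cm.samples, tfs, means, "MRP")
        assert mat.equals(mat2)
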