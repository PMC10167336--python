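import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoclade.phylo_glm import (ancestral_states_continuous,
                                   manova_type2, model_covariance,
                                   model_selection_gic, mvgls_fit)
from morphoclade.synthetic_data import simulate_bm_on_tree, yule_tree
from morphoclade.trees import Phylogeny


def star_tree(n, depth=1.0):
    return Phylogeny([f"s{i}" for i in range(n)],
                     np.array([n] * n + [-1]),
                     np.array([depth] * n + [0.0]))


class TestModelCovariance:
    def test_lambda_scales_off_diagonals(self, small_tree):
        C = small_tree.vcv()
        Ch = model_covariance(small_tree, small_tree.tip_labels,
                              "lambda", 0.5)
        off = ~np.eye(C.shape[0], dtype=bool)
        assert np.allclose(Ch[off], 0.5 * C[off])
        assert np.allclose(np.diag(Ch), np.diag(C))

    def test_eb_limit_is_bm(self, small_tree):
        C = model_covariance(small_tree, small_tree.tip_labels, "EB", -1e-13)
        assert np.allclose(C, small_tree.vcv())

    def test_eb_closed_form(self, small_tree):
        r = -2.0
        C = small_tree.vcv()
        Ceb = model_covariance(small_tree, small_tree.tip_labels, "EB", r)
        assert np.allclose(Ceb, (np.exp(r * C) - 1) / r)

    def test_ou_shrinks_shared_history(self, small_tree):
        Cou = model_covariance(small_tree, small_tree.tip_labels, "OU", 2.0)
        C = small_tree.vcv()
        off = ~np.eye(C.shape[0], dtype=bool)
        # correlations decay under OU relative to BM
        assert (Cou[off] / np.diag(Cou).mean()).mean() < \
               (C[off] / np.diag(C).mean()).mean()


class TestMvgls:
    def test_ols_oracle(self, small_tree):
        """lambda = 0 on an ultrametric tree with no penalty reduces the
        GLS coefficients to ordinary least squares."""
        rng = np.random.default_rng(1)
        n = small_tree.n_tips
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        B = np.array([[1.0, 2.0, 0.5], [0.3, -1.0, 0.8]])
        Y = X @ B + rng.normal(0, 0.5, size=(n, 3))
        fit = mvgls_fit(Y, X, small_tree, small_tree.tip_labels,
                        model="lambda", fixed_param=0.0, penalty_grid=[0.0])
        bols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.abs(fit.beta - bols).max() < 1e-10

    def test_bm_recovery_lambda_near_one(self, small_tree):
        Y = simulate_bm_on_tree(small_tree, np.eye(3), seed=2)
        fit = mvgls_fit(Y, np.ones((small_tree.n_tips, 1)), small_tree,
                        small_tree.tip_labels, model="lambda")
        assert fit.param > 0.9

    def test_beta_recovery_under_bm(self, small_tree):
        rng = np.random.default_rng(3)
        n = small_tree.n_tips
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        B = np.array([[0.0, 0.0], [2.0, -1.0]])
        errs = []
        for i in range(10):
            Y = X @ B + simulate_bm_on_tree(small_tree, 0.25 * np.eye(2),
                                            seed=40 + i)
            fit = mvgls_fit(Y, X, small_tree, small_tree.tip_labels,
                            model="lambda", fixed_param=1.0)
            errs.append(fit.beta[1] - B[1])
        assert np.abs(np.mean(errs, axis=0)).max() < 0.2

    def test_degenerate_identical_traits_warn(self, small_tree):
        Y = np.ones((small_tree.n_tips, 3))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            mvgls_fit(Y, np.ones((small_tree.n_tips, 1)), small_tree,
                      small_tree.tip_labels, model="BM")

    def test_empty_penalty_grid_rejected(self, small_tree):
        Y = simulate_bm_on_tree(small_tree, np.eye(2), seed=4)
        with pytest.raises(ValueError, match="empty"):
            mvgls_fit(Y, np.ones((small_tree.n_tips, 1)), small_tree,
                      small_tree.tip_labels, penalty_grid=[])

    def test_high_dimensional_fit_runs(self, small_tree):
        """More traits than species: the penalised path must produce a
        positive-definite trait covariance."""
        Y = simulate_bm_on_tree(small_tree, np.eye(40), seed=5)
        fit = mvgls_fit(Y, np.ones((small_tree.n_tips, 1)), small_tree,
                        small_tree.tip_labels, model="BM")
        w = np.linalg.eigvalsh(fit.sigma)
        assert w.min() > 0
        assert np.isfinite(fit.gic)


class TestManova:
    def test_star_tree_matches_classical_wilks(self):
        """With a star phylogeny the permutation MANOVA's statistic is
        the classical Wilks' lambda."""
        n = 30
        tree = star_tree(n)
        rng = np.random.default_rng(6)
        grp = np.array(["a"] * 15 + ["b"] * 15)
        Y = rng.normal(size=(n, 3))
        Y[grp == "b"] += 1.0
        tab = manova_type2(Y, pd.DataFrame({"g": grp}), tree,
                           tree.tip_labels, model="BM", n_perm=99, seed=0)
        E = sum((Y[grp == g] - Y[grp == g].mean(0)).T
                @ (Y[grp == g] - Y[grp == g].mean(0)) for g in "ab")
        Ym = Y - Y.mean(0)
        H = Ym.T @ Ym - E
        lam = np.linalg.det(E) / np.linalg.det(E + H)
        assert tab.wilks[0] == pytest.approx(lam, rel=1e-8)
        assert tab.p_values[0] <= 0.05

    def test_null_p_uniform(self, small_tree):
        rng = np.random.default_rng(7)
        n = small_tree.n_tips
        grp = pd.DataFrame({"g": ["a", "b"] * (n // 2)})
        ps = []
        for i in range(60):
            Y = simulate_bm_on_tree(small_tree, np.eye(3), seed=900 + i)
            tab = manova_type2(Y, grp, small_tree, small_tree.tip_labels,
                               model="BM", n_perm=49, seed=i)
            ps.append(tab.p_values[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_type2_term_order_invariance(self, small_tree):
        rng = np.random.default_rng(8)
        n = small_tree.n_tips
        f1 = rng.choice(["x", "y"], n)
        f2 = rng.choice(["u", "v"], n)
        Y = simulate_bm_on_tree(small_tree, np.eye(3), seed=9)
        t1 = manova_type2(Y, pd.DataFrame({"a": f1, "b": f2}), small_tree,
                          small_tree.tip_labels, model="BM", n_perm=29,
                          seed=1)
        t2 = manova_type2(Y, pd.DataFrame({"b": f2, "a": f1}), small_tree,
                          small_tree.tip_labels, model="BM", n_perm=29,
                          seed=1)
        d1 = dict(zip(t1.terms, t1.wilks))
        d2 = dict(zip(t2.terms, t2.wilks))
        assert d1["a"] == pytest.approx(d2["a"], rel=1e-9)
        assert d1["b"] == pytest.approx(d2["b"], rel=1e-9)

    def test_covariate_interaction_terms_present(self, small_tree):
        rng = np.random.default_rng(10)
        n = small_tree.n_tips
        grp = pd.DataFrame({"hab": rng.choice(["r", "s"], n)})
        cs = rng.normal(size=n)
        Y = simulate_bm_on_tree(small_tree, np.eye(4), seed=11)
        tab = manova_type2(Y, grp, small_tree, small_tree.tip_labels,
                           covariate=cs, model="BM", n_perm=29, seed=2)
        assert set(tab.terms) == {"CS", "hab", "CS:hab"}

    def test_single_level_factor_rejected(self, small_tree):
        Y = simulate_bm_on_tree(small_tree, np.eye(2), seed=12)
        grp = pd.DataFrame({"g": ["a"] * small_tree.n_tips})
        with pytest.raises(ValueError):
            manova_type2(Y, grp, small_tree, small_tree.tip_labels,
                         model="BM", n_perm=9)


class TestModelSelection:
    def test_eb_recovered_on_eb_data(self, small_tree):
        wins = 0
        for i in range(15):
            Y = simulate_bm_on_tree(small_tree, 0.01 * np.eye(3),
                                    model="EB", model_param=-3.0,
                                    seed=60 + i)
            fits = model_selection_gic(Y, small_tree, small_tree.tip_labels,
                                       models=("BM", "EB"))
            wins += fits[0].model == "EB"
        assert wins > 7

    def test_bm_data_eb_decay_near_zero(self, small_tree):
        rs = []
        for i in range(8):
            Y = simulate_bm_on_tree(small_tree, np.eye(3), seed=80 + i)
            fit = mvgls_fit(Y, np.ones((small_tree.n_tips, 1)), small_tree,
                            small_tree.tip_labels, model="EB")
            rs.append(fit.param)
        assert np.median(np.abs(rs)) < 1.0

    def test_ranking_invariant_to_branch_rescaling(self, small_tree):
        Y = simulate_bm_on_tree(small_tree, np.eye(3), seed=13)
        f1 = model_selection_gic(Y, small_tree, small_tree.tip_labels,
                                 models=("BM", "EB"))
        f2 = model_selection_gic(Y, small_tree.scale(4.0),
                                 small_tree.tip_labels, models=("BM", "EB"))
        assert [f.model for f in f1] == [f.model for f in f2]


class TestAncestralStates:
    def test_two_tip_closed_forms(self):
        eq = Phylogeny(["A", "B"], np.array([2, 2, -1]),
                       np.array([1.0, 1.0, 0.0]))
        st = ancestral_states_continuous(np.array([0.0, 4.0]), eq,
                                         ["A", "B"])
        assert st[eq.root, 0] == pytest.approx(2.0)
        uneq = Phylogeny(["A", "B"], np.array([2, 2, -1]),
                         np.array([1.0, 3.0, 0.0]))
        st = ancestral_states_continuous(np.array([4.0, 0.0]), uneq,
                                         ["A", "B"])
        # weights proportional to 1/branch: (4/1 + 0/3) / (1 + 1/3)
        assert st[uneq.root, 0] == pytest.approx(3.0)

    def test_full_gls_matrix_oracle(self):
        tree = yule_tree(16, seed=3)
        y = simulate_bm_on_tree(tree, np.array([[1.0]]), seed=4)
        st = ancestral_states_continuous(y, tree, tree.tip_labels)
        full = tree.full_vcv()
        tips = np.arange(16)
        Ctt = full[np.ix_(tips, tips)]
        Ci = np.linalg.inv(Ctt)
        one = np.ones(16)
        mu = (one @ Ci @ y[:, 0]) / (one @ Ci @ one)
        internal = np.arange(16, tree.n_nodes)
        anc = mu + full[np.ix_(internal, tips)] @ Ci @ (y[:, 0] - mu)
        assert np.abs(st[internal, 0] - anc).max() < 1e-9

    def test_zero_length_cherry_warns(self):
        tree = Phylogeny(["A", "B", "C"], np.array([3, 3, 4, 4, -1]),
                         np.array([0.0, 0.0, 1.0, 1.0, 0.0]))
        with pytest.warns(RuntimeWarning):
            ancestral_states_continuous(np.array([1.0, 3.0, 0.0]), tree,
                                        ["A", "B", "C"])


class TestWhitening:
    def test_bm_residuals_uncorrelated_after_transform(self, small_tree):
        """Whitening by the true tree covariance decorrelates
        BM-simulated residuals across species."""
        C = small_tree.vcv()
        L = np.linalg.cholesky(C)
        acc = []
        for i in range(40):
            y = simulate_bm_on_tree(small_tree, np.array([[1.0]]),
                                    seed=300 + i)[:, 0]
            acc.append(np.linalg.solve(L, y))
        W = np.array(acc)
        corr = np.corrcoef(W.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert abs(off.mean()) < 0.05
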