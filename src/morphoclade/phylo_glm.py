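"""Multivariate phylogenetic linear models by penalized likelihood.

The trait matrix Y (species x traits, typically 3p Procrustes
coordinates with more traits than species) is modelled as matrix-normal
with a tree-derived row covariance C(theta) — Brownian motion, Pagel's
lambda, early burst (EB) or Ornstein-Uhlenbeck (OU) transforms — and a
ridge-regularised trait covariance whose shrinkage intensity is chosen
by leave-one-out cross-validated likelihood.  On top of the fit sit a
permutation MANOVA/MANCOVA with type-II sums of squares and Wilks'
lambda (Freedman-Lane residual permutation), model selection by a
generalized information criterion, and maximum-likelihood ancestral
states for continuous traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .trees import Phylogeny

__all__ = [
    "GLSFit", "ManovaTable", "model_covariance", "mvgls_fit",
    "manova_type2", "model_selection_gic", "ancestral_states_continuous",
]


# --------------------------------------------------------------------- #
# tree covariance transforms
# --------------------------------------------------------------------- #
def model_covariance(tree: Phylogeny, labels, model: str,
                     param: float | None = None) -> np.ndarray:
    """Tip covariance under a trait-evolution model.

    lambda: off-diagonals multiplied by ``param`` in [0, 1].
    EB: rate decays as ``exp(r t)`` (``param = r <= 0``), so shared path
    ``s`` maps to ``(exp(r s) - 1) / r``.
    OU: stationary transform with strength ``param = alpha >= 0``.
    """
    C = tree.vcv()
    idx = tree.tip_index(labels)
    C = C[np.ix_(idx, idx)]
    if model in ("BM", "bm") or param is None:
        return C
    if model == "lambda":
        lam = float(np.clip(param, 0.0, 1.0))
        out = C * lam
        np.fill_diagonal(out, np.diag(C))
        return out
    if model in ("EB", "eb"):
        r = float(param)
        if abs(r) < 1e-12:
            return C
        return (np.exp(r * C) - 1.0) / r
    if model in ("OU", "ou"):
        a = float(param)
        if a <= 1e-12:
            return C
        h = np.diag(C)
        d = h[:, None] + h[None, :] - 2 * C
        return (1.0 - np.exp(-2 * a * C)) * np.exp(-a * d) / (2 * a)
    raise ValueError(f"unknown model {model!r}")


_PARAM_BOUNDS = {"lambda": (0.0, 1.0), "EB": (-10.0, 0.0), "OU": (0.0, 50.0)}


# --------------------------------------------------------------------- #
# penalized GLS fit
# --------------------------------------------------------------------- #
@dataclass
class GLSFit:
    beta: np.ndarray              # (q, p_traits)
    sigma: np.ndarray             # regularised trait covariance
    model: str
    param: float | None           # lambda / r / alpha (None for BM)
    penalty: float                # shrinkage intensity delta in [0, 1)
    loglik: float
    gic: float
    residuals: np.ndarray = field(repr=False, default=None)   # whitened
    labels: list = field(repr=False, default=None)


def _gls_core(Y, X, C):
    """Whiten by chol(C); return beta, whitened residuals, logdet C."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular phylogenetic covariance")
    Yw = np.linalg.solve(L, Y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    R = Yw - Xw @ beta
    logdetC = 2.0 * np.log(np.diag(L)).sum()
    return beta, R, logdetC, Xw


def _shrunk(S, delta):
    return (1.0 - delta) * S + delta * np.diag(np.diag(S))


def _loocv_loglik(R, delta):
    """Leave-one-out predictive log-likelihood of whitened residuals
    under the shrunk covariance."""
    n, p = R.shape
    total = 0.0
    S_full = R.T @ R
    for i in range(n):
        Si = (S_full - np.outer(R[i], R[i])) / (n - 1)
        Sd = _shrunk(Si, delta) + 1e-12 * np.eye(p)
        sign, logdet = np.linalg.slogdet(Sd)
        if sign <= 0:
            return -np.inf
        q = R[i] @ np.linalg.solve(Sd, R[i])
        total += -0.5 * (p * np.log(2 * np.pi) + logdet + q)
    return total


def _matrix_normal_loglik(R, Sigma, logdetC, p):
    n = R.shape[0]
    sign, logdetS = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    tr = np.trace(np.linalg.solve(Sigma, R.T @ R))
    return (-0.5 * n * p * np.log(2 * np.pi) - 0.5 * p * logdetC
            - 0.5 * n * logdetS - 0.5 * tr)


def mvgls_fit(Y, X, tree: Phylogeny, labels, model: str = "lambda",
              penalty_grid=None, fixed_param: float | None = None) -> GLSFit:
    """Fit a multivariate phylogenetic linear model.

    The model parameter (lambda, EB decay rate r, or OU strength alpha)
    is optimised by bounded 1-D search; the ridge shrinkage intensity by
    cross-validated likelihood over ``penalty_grid``; more traits than
    species is the intended use case.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = Y.shape
    if penalty_grid is None:
        penalty_grid = np.concatenate([[0.0], np.logspace(-4, -0.05, 9)])
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")

    def fit_at(param):
        C = model_covariance(tree, labels, model, param)
        beta, R, logdetC, _ = _gls_core(Y, X, C)
        if np.allclose(R, 0, atol=1e-12):
            warnings.warn("degenerate residuals: traits identical across "
                          "species after regression", RuntimeWarning)
        best = (-np.inf, penalty_grid[0])
        for d in penalty_grid:
            ll = _loocv_loglik(R, d)
            if ll > best[0]:
                best = (ll, d)
        delta = best[1]
        S = R.T @ R / n
        Sigma = _shrunk(S, delta) + 1e-10 * np.trace(S) / p * np.eye(p)
        ll = _matrix_normal_loglik(R, Sigma, logdetC, p)
        return beta, R, Sigma, delta, ll

    if model in ("BM", "bm") or fixed_param is not None:
        param = fixed_param
        beta, R, Sigma, delta, ll = fit_at(param)
    else:
        lo, hi = _PARAM_BOUNDS[model]
        if model == "EB":
            lo = lo / max(tree.max_height, 1e-9)
        if model == "OU":
            hi = hi / max(tree.max_height, 1e-9)
        res = optimize.minimize_scalar(lambda t: -fit_at(t)[4],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-4 * (hi - lo)})
        param = float(res.x)
        beta, R, Sigma, delta, ll = fit_at(param)

    q = X.shape[1]
    n_theta = 0 if (model in ("BM", "bm") or fixed_param is not None) else 1
    df_sigma = (1 - delta) * p * (p + 1) / 2.0 + delta * p
    gic = -2.0 * ll + 2.0 * (q * p + n_theta + df_sigma)
    return GLSFit(beta, Sigma, model, param, float(delta), float(ll),
                  float(gic), residuals=R, labels=list(labels))


def model_selection_gic(Y, tree: Phylogeny, labels,
                        models=("BM", "EB", "OU"), X=None) -> list:
    """Fit each candidate trait model and rank ascending by GIC."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 8:
        raise ValueError("model selection needs >= 8 species")
    if X is None:
        X = np.ones((Y.shape[0], 1))
    fits = []
    for m in models:
        try:
            fits.append(mvgls_fit(Y, X, tree, labels, model=m))
        except Exception as e:                      # noqa: BLE001
            warnings.warn(f"model {m} failed: {e}", RuntimeWarning)
    return sorted(fits, key=lambda f: f.gic)


# --------------------------------------------------------------------- #
# permutation MANOVA / MANCOVA
# --------------------------------------------------------------------- #
@dataclass
class ManovaTable:
    terms: list
    wilks: np.ndarray
    effect: np.ndarray            # -log(Wilks), a monotone effect size
    p_values: np.ndarray
    n_permutations: int
    model_param: float | None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "wilks": self.wilks,
                             "effect": self.effect, "p": self.p_values
                             }).set_index("term")


def _design_columns(factors: pd.DataFrame, covariate, interactions):
    """Treatment-coded design blocks per term (intercept separate)."""
    blocks = {}
    if covariate is not None:
        blocks["CS"] = np.asarray(covariate, dtype=float)[:, None]
    for col in factors.columns:
        lv = pd.get_dummies(factors[col], drop_first=True).to_numpy(float)
        if lv.shape[1] == 0:
            raise ValueError(f"factor {col!r} has a single level")
        counts = factors[col].value_counts()
        if (counts < 2).any():
            warnings.warn(f"factor {col!r} has levels with < 2 species",
                          RuntimeWarning)
        blocks[col] = lv
    if interactions and covariate is not None:
        for col in factors.columns:
            blocks[f"CS:{col}"] = blocks["CS"] * blocks[col]
    return blocks


def _wilks(E, H):
    lam = np.linalg.det(E) / np.linalg.det(E + H)
    return float(np.clip(lam, 1e-300, 1.0))


def _sscp(Yw, Xw):
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    R = Yw - Xw @ beta
    return R.T @ R, Xw @ beta


def manova_type2(Y, factors: pd.DataFrame, tree: Phylogeny, labels,
                 covariate=None, model: str = "lambda",
                 n_perm: int = 1000, seed: int | None = None,
                 interactions: bool = True) -> ManovaTable:
    """Phylogenetic MANOVA/MANCOVA with type-II terms and Wilks' lambda.

    Each term is tested by comparing the full model with the type-II
    reduced model (all terms except the target and any interaction
    containing it) in the phylogenetically whitened space; significance
    by Freedman-Lane permutation of reduced-model residuals.  When the
    trait count exceeds the residual degrees of freedom, traits are
    first projected on their leading principal components so the
    generalized determinants exist.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    base = mvgls_fit(Y, np.ones((n, 1)), tree, labels, model=model)
    C = model_covariance(tree, labels, model, base.param)
    L = np.linalg.cholesky(C)
    Yw = np.linalg.solve(L, Y)

    blocks = _design_columns(factors, covariate, interactions)
    terms = list(blocks)
    ones = np.ones((n, 1))
    Xfull = np.column_stack([ones] + [blocks[t] for t in terms])
    Xw_full = np.linalg.solve(L, Xfull)

    rank_full = np.linalg.matrix_rank(Xw_full)
    df_resid = n - rank_full
    if Y.shape[1] > df_resid - 1:
        k = max(1, df_resid - 1)
        Zc = Yw - Yw.mean(axis=0)
        _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
        Yw = Yw @ Vt[:k].T

    rng = np.random.default_rng(seed)
    wilks = np.empty(len(terms))
    pvals = np.empty(len(terms))
    E_full, _ = _sscp(Yw, Xw_full)

    for ti, term in enumerate(terms):
        def contains(other):    # interactions containing the target term
            return other != term and term in other.split(":")
        reduced_terms = [t for t in terms if t != term and not contains(t)]
        X_red = np.column_stack([ones] + [blocks[t] for t in reduced_terms]) \
            if reduced_terms else ones
        X_aug = np.column_stack([X_red, blocks[term]])
        Xw_red = np.linalg.solve(L, X_red)
        Xw_aug = np.linalg.solve(L, X_aug)

        E_red, fit_red = _sscp(Yw, Xw_red)
        E_aug, _ = _sscp(Yw, Xw_aug)
        H = E_red - E_aug
        lam_obs = _wilks(E_aug, H)
        R_red = Yw - fit_red
        hits = 0
        for _ in range(n_perm):
            Ystar = fit_red + R_red[rng.permutation(n)]
            E_r, _ = _sscp(Ystar, Xw_red)
            E_a, _ = _sscp(Ystar, Xw_aug)
            if _wilks(E_a, E_r - E_a) <= lam_obs:
                hits += 1
        wilks[ti] = lam_obs
        pvals[ti] = (hits + 1) / (n_perm + 1)

    effect = -np.log(wilks)
    return ManovaTable(terms, wilks, effect, pvals, n_perm, base.param)


# --------------------------------------------------------------------- #
# ancestral states
# --------------------------------------------------------------------- #
def ancestral_states_continuous(Y, tree: Phylogeny, labels) -> np.ndarray:
    """Maximum-likelihood (GLS) Brownian-motion ancestral states.

    Returns an array over all nodes (tips included, in tree node order);
    the root of a two-tip tree is the branch-length-inverse-weighted
    average of the tip values.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    idx = tree.tip_index(labels)
    full = tree.full_vcv()
    tips = np.arange(tree.n_tips)
    Ctt = full[np.ix_(tips, tips)]
    zero_cherry = False
    if np.linalg.matrix_rank(Ctt) < len(tips):
        zero_cherry = True
        Ctt = Ctt + 1e-10 * np.eye(len(tips))
        warnings.warn("zero-length branches: ancestral weights regularised "
                      "toward equal", RuntimeWarning)
    Yt = np.empty_like(Y)
    Yt[idx] = Y
    Cinv = np.linalg.inv(Ctt)
    one = np.ones(tree.n_tips)
    mu = (one @ Cinv @ Yt) / (one @ Cinv @ one)
    states = np.empty((tree.n_nodes, Y.shape[1]))
    states[tips] = Yt
    internal = np.arange(tree.n_tips, tree.n_nodes)
    Cnt = full[np.ix_(internal, tips)]
    states[internal] = mu + Cnt @ Cinv @ (Yt - mu)
    if zero_cherry:
        pass
    return states
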