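"""Shape ordinations, phylogenetic signal and functional proxies.

``pca`` is an ordinary SVD-based principal component analysis of the
species (or specimen) shape matrix.  ``papca`` is the phylogenetically
aligned component analysis of Collyer & Adams: data are centred on the
generalized-least-squares (phylogenetic) mean and axes are obtained
from the eigendecomposition of the cross-product between the data and
its projection through the tree covariance, so the leading axes are
those most aligned with phylogenetic signal; explained percentages are
reported relative to total data variance.  ``kmult`` is the
multivariate generalisation of Blomberg's K with a permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Phylogeny

__all__ = [
    "OrdinationResult", "SignalResult", "FunctionalProxies",
    "pca", "papca", "kmult", "meaningful_pcs", "functional_correlations",
    "phylomorphospace_coords", "mechanical_advantage", "symphysis_depth",
]


@dataclass
class OrdinationResult:
    scores: np.ndarray            # (n, k)
    loadings: np.ndarray          # (d, k), orthonormal columns
    eigenvalues: np.ndarray
    percent_variance: np.ndarray  # per axis, relative to total variance
    center: np.ndarray
    kind: str                     # 'pca' | 'papca'
    labels: list | None = None


@dataclass
class SignalResult:
    k_mult: float
    p_value: float
    n_permutations: int


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic axis orientation: largest-|loading| entry positive."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def pca(shape_matrix: np.ndarray, labels=None) -> OrdinationResult:
    """Principal component analysis of the column-centred matrix."""
    Y = np.asarray(shape_matrix, dtype=float)
    if Y.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    center = Y.mean(axis=0)
    Z = Y - center
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    n = Y.shape[0]
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    if total == 0:
        warnings.warn("constant matrix: all eigenvalues zero", RuntimeWarning)
        pct = np.zeros_like(eig)
    else:
        pct = 100.0 * eig / total
    loadings, scores = _fix_signs(Vt.T.copy(), (U * s).copy())
    return OrdinationResult(scores, loadings, eig, pct, center, "pca", labels)


def _phylo_weights(tree: Phylogeny, labels) -> tuple:
    C = tree.vcv()
    idx = tree.tip_index(labels)
    C = C[np.ix_(idx, idx)]
    Cinv = np.linalg.inv(C)
    one = np.ones(len(labels))
    w = Cinv @ one / (one @ Cinv @ one)
    return C, Cinv, w


def papca(shape_matrix: np.ndarray, tree: Phylogeny,
          labels: list) -> OrdinationResult:
    """Phylogenetically aligned component analysis (aligned variant).

    With an identity tree covariance (star tree of equal depths) the
    axes coincide with ordinary PCA axes.
    """
    Y = np.asarray(shape_matrix, dtype=float)
    C, _, w = _phylo_weights(tree, labels)
    gls_mean = w @ Y
    Z = Y - gls_mean
    n = Y.shape[0]
    # alignment matrix: cross-product of data with its projection
    # through the (centred) tree covariance
    H = np.eye(n) - np.ones((n, n)) / n
    P = H @ C @ H
    S = Z.T @ P @ Z
    S = 0.5 * (S + S.T)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    k = min(n - 1, Y.shape[1])
    V = eigvec[:, order[:k]]
    scores = Z @ V
    axis_var = (scores ** 2).sum(axis=0) / (n - 1)
    total = (Z ** 2).sum() / (n - 1)
    pct = 100.0 * axis_var / total if total > 0 else np.zeros(k)
    V, scores = _fix_signs(V.copy(), scores)
    return OrdinationResult(scores, V, axis_var, pct, gls_mean, "papca",
                            list(labels))


def kmult(shape_matrix: np.ndarray, tree: Phylogeny, labels: list,
          n_perm: int = 1000, seed: int | None = None) -> SignalResult:
    """Multivariate phylogenetic signal (Adams' K_mult).

    Ratio of the observed mean squared deviation from the phylogenetic
    mean in ordinary vs phylogenetically whitened space, scaled by its
    Brownian-motion expectation on the tree; K = 1 is BM-like.
    Significance by permuting species across tips.
    """
    Y = np.atleast_2d(np.asarray(shape_matrix, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    if n < 4:
        raise ValueError("K_mult needs at least 4 species")
    C, Cinv, w = _phylo_weights(tree, labels)
    one = np.ones(n)
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    # eigendecomposition-based inverse square root for the denominator
    L = np.linalg.cholesky(C)

    def stat(Ym):
        a = w @ Ym
        R = Ym - a
        num = (R ** 2).sum()
        Rw = np.linalg.solve(L, R)
        den = (Rw ** 2).sum()
        return (num / den) / expected

    obs = stat(Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(Y[perm]) >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return SignalResult(float(obs), float(p), n_perm)


def meaningful_pcs(ordination: OrdinationResult, n_obs: int,
                   alpha: float = 0.05) -> int:
    """Number of axes to retain by a sequential log-likelihood-ratio
    (sphericity) test on the eigenvalue spectrum.

    For each candidate k, Anderson's statistic tests whether the
    remaining eigenvalues are equal (pure isotropic noise); the smallest
    k whose remainder is homogeneous at ``alpha`` is returned.
    """
    eig = np.asarray(ordination.eigenvalues, dtype=float)
    eig = eig[eig > 1e-12 * max(eig.max(), 1.0)]
    m = len(eig)
    if m < 2:
        return 1
    for k in range(0, m - 1):
        rest = eig[k:]
        q = len(rest)
        lnL = q * np.log(rest.mean()) - np.log(rest).sum()
        statv = (n_obs - k - (2 * q + 11) / 6.0) * lnL
        df = (q + 2) * (q - 1) / 2
        pval = stats.chi2.sf(max(statv, 0.0), df)
        if pval > alpha:
            return max(k, 1)
    return m - 1


def functional_correlations(proxy: np.ndarray, ordination: OrdinationResult,
                            axis: int = 0) -> tuple:
    """Pearson correlation between a functional proxy and one axis'
    scores, with the two-sided t-distribution p-value."""
    x = np.asarray(proxy, dtype=float)
    y = ordination.scores[:, axis]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------- #
# functional proxies
# --------------------------------------------------------------------- #
@dataclass
class FunctionalProxies:
    """Lever-based proxies computed from aligned coordinates.

    MA (mechanical advantage) = in-lever / out-lever; in-lever from the
    articular-condyle landmark to the centroid of the adductor-insertion
    surface landmarks, out-lever from the condyle to the anterior
    symphysis landmark.  Landmark indices are configurable because the
    anatomical correspondences depend on the digitising scheme.
    """

    ma: np.ndarray
    symphysis_depth: np.ndarray
    definitions: dict


def mechanical_advantage(coords: np.ndarray, condyle: int, symphysis: int,
                         adductor_ids) -> np.ndarray:
    """MA per configuration from a (n, p, 3) coordinate block."""
    coords = np.asarray(coords, dtype=float)
    out_lever = np.linalg.norm(coords[:, condyle] - coords[:, symphysis],
                               axis=1)
    insertion = coords[:, list(adductor_ids)].mean(axis=1)
    in_lever = np.linalg.norm(coords[:, condyle] - insertion, axis=1)
    if np.any(out_lever == 0):
        raise ValueError("zero out-lever length")
    return in_lever / out_lever


def symphysis_depth(coords: np.ndarray, upper: int, lower: int) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return np.linalg.norm(coords[:, upper] - coords[:, lower], axis=1)


def phylomorphospace_coords(ordination: OrdinationResult, tree: Phylogeny,
                            node_states: np.ndarray) -> dict:
    """Tip and ancestor scores plus tree edges for phylomorphospace plots.

    ``node_states`` are continuous ancestral estimates for the full
    (3p-dimensional) shape at every node, projected here on the
    ordination's axes.
    """
    anc_scores = (node_states - ordination.center) @ ordination.loadings
    edges = [(int(tree.parent[i]), int(i))
             for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    return {"tip_scores": ordination.scores, "node_scores": anc_scores,
            "edges": edges}
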