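"""Regime-specific Brownian rates, disparity, and disparity through time.

Rates: tip shapes are modelled as multivariate Brownian motion whose
expected species covariance is ``sum_k sigma2_k C_k``, where ``C_k`` is
the shared branch length each species pair spends in regime k of a
stochastic character map.  A common trait structure is assumed with
regime-specific scalars; the reported per-regime rate is the mean of
the regime rate-matrix diagonal across trait dimensions.

Disparity: Procrustes variance (sum of per-coordinate variances around
the group mean) with within-group bootstrap and pairwise Wilcoxon
rank-sum tests, Bonferroni-adjusted.  Disparity through time follows
the classic average-subclade-disparity curve against a
rate-matched Brownian envelope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import Phylogeny

__all__ = [
    "RegimeRates", "DisparityResult", "DTTCurve", "regime_bm_rates",
    "rate_fold_changes", "per_landmark_rates", "group_disparity",
    "procrustes_variance", "dtt",
]


# --------------------------------------------------------------------- #
# regime-specific BM rates
# --------------------------------------------------------------------- #
@dataclass
class RegimeRates:
    regimes: list
    rates: dict                    # regime -> scalar rate (mean across maps)
    rates_sd: dict                 # SD across maps
    per_map: pd.DataFrame          # map x regime scalar rates
    trait_rates: dict = field(repr=False, default=None)
    # regime -> per-trait rate vector (mean across maps)
    unstable: list = field(default_factory=list)


def _fit_one_map(Y, tree, labels, regime_bl, regimes):
    """Profile-likelihood fit of regime scalars for one character map.

    Returns (scalars rho with rho[0]=1 reference removed -- absolute
    per-trait rates sigma2[j] under each regime are rho_k * s2[j]).
    """
    n, p = Y.shape
    idx = tree.tip_index(labels)
    Ck = []
    for rg in regimes:
        C = tree.vcv(branch_lengths=regime_bl[rg])
        Ck.append(C[np.ix_(idx, idx)])
    one = np.ones((n, 1))

    def profile(log_rho):
        # relative scalars bounded to a broad but finite range so regimes
        # with negligible exposure cannot run away to 0 or infinity
        rho = np.concatenate([[1.0], np.exp(np.clip(log_rho, -11.5, 11.5))])
        C = sum(r * c for r, c in zip(rho, Ck))
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        Yw = np.linalg.solve(L, Y)
        ow = np.linalg.solve(L, one)
        mu = (ow.T @ Yw) / (ow.T @ ow)
        R = Yw - ow @ mu
        s2 = (R ** 2).sum(axis=0) / n
        s2 = np.maximum(s2, 1e-300)
        logdetC = 2 * np.log(np.diag(L)).sum()
        ll = -0.5 * n * np.log(2 * np.pi * s2).sum() \
             - 0.5 * p * logdetC - 0.5 * n * p
        return -ll, rho, s2

    k = len(regimes)
    if k == 1:
        _, rho, s2 = profile(np.array([]))
        return rho, s2
    best = None
    for start in ([np.zeros(k - 1)] +
                  [np.full(k - 1, v) for v in (-1.0, 1.0)]):
        res = optimize.minimize(lambda x: profile(x)[0], start,
                                method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    _, rho, s2 = profile(best.x)
    return rho, s2


def regime_bm_rates(species_matrix: np.ndarray, labels,
                    regime_maps: list) -> RegimeRates:
    """Regime-specific Brownian rate scalars from character maps.

    Each map contributes one maximum-likelihood fit; summaries (mean,
    SD) aggregate across maps.  Regimes occupying < 1% of total tree
    length are flagged as unstable.
    """
    Y = np.asarray(species_matrix, dtype=float)
    regimes = sorted({st for m in regime_maps for st in m.states})
    rows = []
    trait_acc = {rg: [] for rg in regimes}
    unstable = set()
    for m in regime_maps:
        bl = m.regime_branch_lengths()
        for rg in regimes:
            if rg not in bl:
                bl[rg] = np.zeros(m.tree.n_nodes)
        total = m.tree.branch_lengths.sum()
        present = [rg for rg in regimes if bl[rg].sum() > 0]
        for rg in present:
            if bl[rg].sum() < 0.01 * total:
                unstable.add(rg)
        rho, s2 = _fit_one_map(Y, m.tree, labels,
                               {rg: bl[rg] for rg in present}, present)
        row = {}
        for rg, r in zip(present, rho):
            row[rg] = r * s2.mean()
            trait_acc[rg].append(r * s2)
        rows.append(row)
    per_map = pd.DataFrame(rows)
    if unstable:
        warnings.warn(f"regimes {sorted(unstable)} occupy < 1% of tree "
                      "length; estimates unstable", RuntimeWarning)
    rates = {rg: float(per_map[rg].mean()) for rg in per_map.columns}
    rates_sd = {rg: float(per_map[rg].std(ddof=0)) for rg in per_map.columns}
    trait_rates = {rg: np.mean(trait_acc[rg], axis=0)
                   for rg in regimes if trait_acc[rg]}
    return RegimeRates(list(per_map.columns), rates, rates_sd, per_map,
                       trait_rates, sorted(unstable))


def rate_fold_changes(rates: dict, reference: str | None = None,
                      digits: int = 3) -> pd.DataFrame:
    """Pairwise rate ratios ``sigma_A / sigma_B`` rounded for reporting.

    With ``reference`` set, only the column against that regime is
    returned.
    """
    regimes = list(rates)
    if len(regimes) < 2:
        raise ValueError("fold changes need >= 2 regimes")
    for rg, v in rates.items():
        if v == 0:
            raise ZeroDivisionError(f"zero rate for regime {rg!r}")
    tab = pd.DataFrame(
        [[round(rates[a] / rates[b], digits) for b in regimes]
         for a in regimes], index=regimes, columns=regimes)
    if reference is not None:
        return tab[[reference]]
    return tab


def per_landmark_rates(species_matrix: np.ndarray, labels,
                       regime_maps: list, scheme) -> pd.DataFrame:
    """Landmark x regime rate table: the per-trait regime rates summed
    over each landmark's three coordinates."""
    rr = regime_bm_rates(species_matrix, labels, regime_maps)
    p = scheme.p
    rows = {}
    for rg, tr in rr.trait_rates.items():
        rows[rg] = tr.reshape(p, 3).sum(axis=1)
    return pd.DataFrame(rows, index=[f"lm{i}" for i in range(p)])


# --------------------------------------------------------------------- #
# disparity
# --------------------------------------------------------------------- #
def procrustes_variance(X: np.ndarray) -> float:
    """Sum of per-coordinate variances around the mean shape (the
    'sum of variances' disparity metric); 0 for a single row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 0.0
    dev = X - X.mean(axis=0)
    return float((dev ** 2).sum() / X.shape[0])


@dataclass
class DisparityResult:
    groups: list
    pv: dict
    bootstrap: dict                 # group -> (n_boot,) PV draws
    p_matrix: pd.DataFrame          # Bonferroni-adjusted Wilcoxon p
    raw_p_matrix: pd.DataFrame


def group_disparity(species_matrix: np.ndarray, grouping, n_boot: int = 100,
                    seed: int | None = None,
                    rarefy: bool = False) -> DisparityResult:
    """Per-group Procrustes variance with bootstrap and pairwise tests.

    Species are resampled with replacement within each group (optionally
    rarefied to the smallest group size); group pairs are compared by a
    two-sided Wilcoxon rank-sum test on the bootstrap distributions with
    Bonferroni correction over the number of pairs.
    """
    Y = np.asarray(species_matrix, dtype=float)
    grouping = np.asarray(grouping)
    groups = sorted(set(grouping))
    rng = np.random.default_rng(seed)
    members = {g: np.where(grouping == g)[0] for g in groups}
    pv = {g: procrustes_variance(Y[members[g]]) for g in groups}
    testable = []
    for g in groups:
        if len(members[g]) < 3:
            warnings.warn(f"group {g!r} has < 3 species; excluded from "
                          "tests", RuntimeWarning)
        else:
            testable.append(g)
    draw_n = min(len(members[g]) for g in groups) if rarefy else None
    boot = {}
    for g in groups:
        m = members[g]
        size = draw_n if rarefy else len(m)
        bs = np.empty(n_boot)
        for b in range(n_boot):
            bs[b] = procrustes_variance(Y[rng.choice(m, size=size,
                                                     replace=True)])
        boot[g] = bs
    pairs = list(itertools.combinations(testable, 2))
    raw = pd.DataFrame(np.nan, index=groups, columns=groups)
    adj = raw.copy()
    for a, b in pairs:
        _, p = stats.mannwhitneyu(boot[a], boot[b], alternative="two-sided")
        raw.loc[a, b] = raw.loc[b, a] = p
        adj.loc[a, b] = adj.loc[b, a] = min(p * len(pairs), 1.0)
    return DisparityResult(groups, pv, boot, adj, raw)


# --------------------------------------------------------------------- #
# disparity through time
# --------------------------------------------------------------------- #
@dataclass
class DTTCurve:
    times: np.ndarray               # relative node heights in [0, 1]
    observed: np.ndarray            # relative mean subclade disparity
    sim_mean: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    mdi: float                      # area between observed and sim mean
    n_sim: int


def _dtt_curve(Y, tree, tip_to_row):
    """Average relative subclade disparity at every internal node height;
    ``tip_to_row`` maps tree tip indices to rows of ``Y``."""
    masks = tree.clade_masks()
    heights = tree.node_heights()
    total = procrustes_variance(Y)
    if total == 0:
        raise ValueError("zero total disparity")
    internal = [nd for nd in range(tree.n_nodes) if tree.children[nd]]
    order = sorted(internal, key=lambda nd: heights[nd])
    times, vals = [], []
    for nd in order:
        t = heights[nd]
        # lineages crossing just after t: nodes whose branch spans t
        live = [x for x in range(tree.n_nodes)
                if tree.parent[x] >= 0
                and heights[tree.parent[x]] <= t < heights[x]]
        if heights[nd] == 0:                       # the root itself
            live = tree.children[nd] if not live else live
        ds = []
        for x in live:
            tips = np.where(masks[x])[0]
            ds.append(procrustes_variance(Y[tip_to_row[tips]]) / total
                      if len(tips) > 1 else 0.0)
        times.append(t)
        vals.append(np.mean(ds) if ds else 0.0)
    T = tree.max_height
    times = np.array(times) / T
    vals = np.array(vals)
    if times[0] == 0:
        vals[0] = 1.0               # whole clade at the root
    else:
        times = np.concatenate([[0.0], times])
        vals = np.concatenate([[1.0], vals])
    return times, vals


def dtt(species_matrix: np.ndarray, tree: Phylogeny, labels,
        n_sim: int = 1000, seed: int | None = None) -> DTTCurve:
    """Disparity-through-time curve with a Brownian null envelope.

    The observed mean relative subclade disparity is evaluated at every
    internal-node height; ``n_sim`` Brownian simulations, rate-matched
    to the data per trait, give the per-time 95% band and the
    area-between-curves (MDI-style) statistic.
    """
    Y = np.asarray(species_matrix, dtype=float)
    if tree.n_tips < 4:
        raise ValueError("DTT needs >= 4 tips")
    if not tree.is_ultrametric(tol=1e-4):
        raise ValueError("DTT requires an ultrametric tree; time-scale the "
                         "tree (all tips equidistant from the root) first")
    idx = tree.tip_index(labels)
    inv = np.empty_like(idx)
    inv[idx] = np.arange(len(idx))   # tree tip -> row of Y
    times, observed = _dtt_curve(Y, tree, inv)

    # rate-matched BM simulations
    C = tree.vcv()[np.ix_(idx, idx)]
    L = np.linalg.cholesky(C)
    n, p = Y.shape
    one = np.ones((n, 1))
    Yw = np.linalg.solve(L, Y)
    ow = np.linalg.solve(L, one)
    mu = (ow.T @ Yw) / (ow.T @ ow)
    R = Yw - ow @ mu
    s2 = (R ** 2).sum(axis=0) / n
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(times)))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p)) * np.sqrt(s2)
        Ysim = L @ Z
        _, sims[s] = _dtt_curve(Ysim, tree, inv)
    lo = np.percentile(sims, 2.5, axis=0)
    hi = np.percentile(sims, 97.5, axis=0)
    mean = sims.mean(axis=0)
    mdi = float(np.trapezoid(observed - mean, times))
    return DTTCurve(times, observed, mean, lo, hi, mdi, n_sim)
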