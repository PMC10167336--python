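"""Mk models for discrete characters and stochastic character mapping.

The likelihood is Felsenstein's pruning algorithm with per-branch
transition matrices ``expm(Q t)``; rate matrices may be constrained to
equal rates (ER), symmetric (SYM) or all-rates-different (ARD).
``simmap`` draws full substitution histories along branches conditional
on the tip data, sampling node states from their joint conditional
distribution and branch histories by uniformisation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .trees import Phylogeny

__all__ = [
    "MkFit", "RegimeMap", "build_q", "mk_loglik", "fit_mk",
    "marginal_ancestral_states", "simmap",
]


# --------------------------------------------------------------------- #
# rate matrices
# --------------------------------------------------------------------- #
def build_q(rates: np.ndarray, n_states: int, structure: str) -> np.ndarray:
    """Assemble Q from a free-rate vector under a structure constraint."""
    Q = np.zeros((n_states, n_states))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        k = 0
        for i in range(n_states):
            for j in range(i + 1, n_states):
                Q[i, j] = Q[j, i] = rates[k]
                k += 1
    elif structure == "ARD":
        k = 0
        for i in range(n_states):
            for j in range(n_states):
                if i != j:
                    Q[i, j] = rates[k]
                    k += 1
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def n_free_rates(n_states: int, structure: str) -> int:
    return {"ER": 1, "SYM": n_states * (n_states - 1) // 2,
            "ARD": n_states * (n_states - 1)}[structure]


def _validate_q(Q: np.ndarray):
    Q = np.asarray(Q, dtype=float)
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("negative off-diagonal rates")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(np.abs(Q).max(), 1.0)):
        raise ValueError("Q rows must sum to 0")
    return Q


def _transition(Q: np.ndarray, t: float) -> np.ndarray:
    """``expm(Q t)`` by eigendecomposition, scaling-and-squaring fallback."""
    try:
        w, V = np.linalg.eig(Q)
        P = (V * np.exp(w * t)) @ np.linalg.inv(V)
        P = P.real
        if np.any(P < -1e-8):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = linalg.expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------- #
# pruning likelihood
# --------------------------------------------------------------------- #
def _tip_partials(tree: Phylogeny, tip_states: dict, states: list):
    s = len(states)
    idx = {st: i for i, st in enumerate(states)}
    L = np.zeros((tree.n_nodes, s))
    for i, lab in enumerate(tree.tip_labels):
        st = tip_states.get(lab)
        if st is None:
            L[i] = 1.0            # missing: all-ones partial
        else:
            L[i, idx[st]] = 1.0
    return L


def _transition_batch(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """``expm(Q t)`` for many branch lengths from one eigendecomposition;
    falls back to per-branch scaling-and-squaring for defective Q."""
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(ts, w)), Vinv).real
        if np.any(P < -1e-8):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * t) for t in ts])
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=2, keepdims=True)


def _up_pass(tree: Phylogeny, Q: np.ndarray, L: np.ndarray):
    """Conditional likelihoods up the tree with per-node scaling."""
    nodes = [nd for nd in range(tree.n_nodes) if tree.parent[nd] >= 0]
    Pb = _transition_batch(Q, tree.branch_lengths[nodes])
    P = {nd: Pb[i] for i, nd in enumerate(nodes)}
    L = L.copy()
    logscale = 0.0
    for nd in tree.postorder:
        if tree.children[nd]:
            part = np.ones(L.shape[1])
            for ch in tree.children[nd]:
                part = part * (P[ch] @ L[ch])
            mx = part.max()
            if mx <= 0:
                return L, -np.inf, P
            L[nd] = part / mx
            logscale += np.log(mx)
    return L, logscale, P


def _root_weights(root_partial: np.ndarray, Q: np.ndarray,
                  root_prior: str) -> np.ndarray:
    s = len(root_partial)
    if root_prior == "equal":
        return np.full(s, 1.0 / s)
    if root_prior == "stationary":
        w, V = np.linalg.eig(Q.T)
        pi = np.abs(V[:, np.argmin(np.abs(w))].real)
        return pi / pi.sum()
    if root_prior == "fitzjohn":
        tot = root_partial.sum()
        return (root_partial / tot if tot > 0
                else np.full(s, 1.0 / s))
    raise ValueError(f"unknown root prior {root_prior!r}")


def mk_loglik(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
              states: list | None = None,
              root_prior: str = "fitzjohn") -> float:
    """Log-likelihood of discrete tip data under an Mk rate matrix."""
    Q = _validate_q(Q)
    if states is None:
        states = sorted({v for v in tip_states.values() if v is not None})
    L = _tip_partials(tree, tip_states, states)
    L, logscale, _ = _up_pass(tree, Q, L)
    root = L[tree.root]
    pi = _root_weights(root, Q, root_prior)
    lik = float(root @ pi)
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #
@dataclass
class MkFit:
    states: list
    Q: np.ndarray
    structure: str
    loglik: float
    aic: float
    root_prior: str
    converged: bool = True


def fit_mk(tree: Phylogeny, tip_states: dict, structure: str = "ER",
           root_prior: str = "fitzjohn", n_starts: int = 3,
           seed: int | None = None) -> MkFit:
    """Maximum-likelihood Mk fit with log-parameterised rates and
    multi-start quasi-Newton optimisation."""
    states = sorted({v for v in tip_states.values() if v is not None})
    if len(states) < 2:
        warnings.warn("single observed state: degenerate fit at the rate "
                      "lower bound", RuntimeWarning)
        Q = build_q(np.full(n_free_rates(2, structure), 1e-8), 2, structure)
        ll = 0.0
        k = n_free_rates(2, structure)
        return MkFit(states, Q, structure, ll, 2 * k - 2 * ll, root_prior)
    s = len(states)
    k = n_free_rates(s, structure)
    rng = np.random.default_rng(seed)

    def nll(logr):
        Q = build_q(np.exp(logr), s, structure)
        return -mk_loglik(tree, tip_states, Q, states, root_prior)

    # coarse scan over a common rate to seed the starts (the surface has
    # a flat saturated plateau at high rates that traps line searches)
    grid = np.linspace(-7.0, 5.0, 13)
    g0 = grid[int(np.argmin([nll(np.full(k, g)) for g in grid]))]
    best = None
    bounds = [(-12.0, 8.0)] * k
    for start in range(n_starts):
        x0 = np.full(k, g0) + (0 if start == 0 else rng.normal(0, 0.7, k))
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 4000})
        res.x = np.clip(res.x, bounds[0][0], bounds[0][1])
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    if np.any(best.x > 7.9):
        warnings.warn("rates at the upper bound (saturation)", RuntimeWarning)
    Q = build_q(rates, s, structure)
    ll = -float(best.fun)
    return MkFit(states, Q, structure, ll, 2 * k - 2 * ll, root_prior,
                 converged=bool(best.success))


# --------------------------------------------------------------------- #
# marginal ancestral states
# --------------------------------------------------------------------- #
def marginal_ancestral_states(tree: Phylogeny, tip_states: dict,
                              Q: np.ndarray, states: list | None = None,
                              root_prior: str = "fitzjohn") -> np.ndarray:
    """Marginal posterior state probabilities at every node (rows sum
    to 1; tip rows are their observed indicators)."""
    Q = _validate_q(Q)
    if states is None:
        states = sorted({v for v in tip_states.values() if v is not None})
    L = _tip_partials(tree, tip_states, states)
    up, _, P = _up_pass(tree, Q, L)
    s = len(states)
    down = np.zeros((tree.n_nodes, s))
    root = tree.root
    down[root] = _root_weights(up[root], Q, root_prior)
    for nd in tree.preorder():
        for ch in tree.children[nd]:
            other = down[nd].copy()
            for sib in tree.children[nd]:
                if sib != ch:
                    other *= P[sib] @ up[sib]
            down[ch] = other @ P[ch]
            mx = down[ch].max()
            if mx > 0:
                down[ch] /= mx
    post = up * down
    tot = post.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return post / tot


# --------------------------------------------------------------------- #
# stochastic character mapping
# --------------------------------------------------------------------- #
@dataclass
class RegimeMap:
    """A sampled substitution history: ordered (state, duration)
    segments per branch, rootward first."""

    tree: Phylogeny
    states: list
    segments: dict = field(repr=False)        # node -> [(state, duration)]
    node_states: np.ndarray = field(repr=False, default=None)
    map_id: int = 0
    seed: int | None = None

    def validate(self, tol: float = 1e-9):
        for nd, segs in self.segments.items():
            total = sum(d for _, d in segs)
            bl = self.tree.branch_lengths[nd]
            if abs(total - bl) > tol * max(bl, 1.0):
                raise AssertionError(
                    f"segment durations on branch {nd} sum to {total}, "
                    f"branch length {bl}")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise AssertionError("adjacent segments share a state")
            if nd < self.tree.n_tips and segs:
                if segs[-1][0] != self.states[self.node_states[nd]]:
                    raise AssertionError("tipward segment state mismatch")
        return True

    def tip_state(self, label: str) -> str:
        i = self.tree.tip_labels.index(label)
        return self.states[self.node_states[i]]

    def n_changes(self) -> int:
        return sum(max(len(s) - 1, 0) for s in self.segments.values())

    def regime_branch_lengths(self) -> dict:
        """Per-regime branch-length arrays (node-indexed), for building
        regime covariance matrices."""
        out = {st: np.zeros(self.tree.n_nodes) for st in self.states}
        for nd, segs in self.segments.items():
            for st, dur in segs:
                out[st][nd] += dur
        return out

    def to_json(self) -> str:
        return json.dumps({
            "states": self.states, "map_id": self.map_id, "seed": self.seed,
            "newick": self.tree.to_newick(),
            "node_states": self.node_states.tolist(),
            "segments": {str(k): v for k, v in self.segments.items()},
        })

    def to_annotated_newick(self) -> str:
        ann = {nd: "map=" + ",".join(f"{st}:{dur:.8g}" for st, dur in segs)
               for nd, segs in self.segments.items() if segs}
        return self.tree.to_newick(annotations=ann)


def _sample_branch_history(Q, i, j, t, rng, states, max_reject=10_000):
    """Substitution history on one branch conditional on endpoint states
    (i rootward, j tipward), by uniformisation."""
    s = Q.shape[0]
    if t <= 0:
        return [(states[j], 0.0)] if i == j else None
    omega = max(-Q.diagonal().min(), 1e-12)
    R = np.eye(s) + Q / omega
    Pt = _transition(Q, t)
    if Pt[i, j] <= 0:
        raise ValueError("conditioning on a zero-probability endpoint pair")
    # number of uniformised jumps
    Rpow = [np.eye(s)]
    probs = []
    lam = omega * t
    logpois = -lam
    n = 0
    acc = 0.0
    while acc < 1.0 - 1e-12 and n < 10_000:
        pn = np.exp(logpois + n * np.log(lam) - _logfact(n)) if lam > 0 else (
            1.0 if n == 0 else 0.0)
        probs.append(pn * Rpow[-1][i, j] / Pt[i, j])
        acc += probs[-1]
        Rpow.append(Rpow[-1] @ R)
        n += 1
    probs = np.clip(np.array(probs), 0, None)
    tot = probs.sum()
    if tot <= 0:
        raise ValueError("endpoint-conditioned jump distribution degenerate")
    n_jumps = rng.choice(len(probs), p=probs / tot)
    # state sequence via backward sampling through R powers
    seq = [i]
    for step in range(n_jumps):
        remain = n_jumps - step - 1
        cur = seq[-1]
        w = R[cur, :] * Rpow[remain][:, j]
        w = np.clip(w, 0, None)
        if w.sum() <= 0:
            w = np.ones(s)
        seq.append(rng.choice(s, p=w / w.sum()))
    if seq[-1] != j:
        seq[-1] = j    # guard; cannot differ when weights are exact
    times = np.sort(rng.uniform(0, t, size=n_jumps))
    # collapse virtual (self) transitions into segments
    segs = []
    cur, t0 = seq[0], 0.0
    for st, tm in zip(seq[1:], times):
        if st != cur:
            segs.append((states[cur], tm - t0))
            cur, t0 = st, tm
    segs.append((states[cur], t - t0))
    return segs


_LOGFACT = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, 10_001)))])


def _logfact(n):
    return _LOGFACT[n]


def simmap(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
           n_maps: int = 1, seed: int | None = None,
           states: list | None = None,
           root_prior: str = "fitzjohn") -> list:
    """Stochastic character maps conditional on the tip data.

    Node states are drawn from their joint conditional distribution by a
    root-to-tip pass over the pruning partials, then branch histories by
    endpoint-conditioned uniformisation.  Reproducible per
    ``(seed, map index)``.
    """
    Q = _validate_q(Q)
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if states is None:
        states = sorted({v for v in tip_states.values() if v is not None})
    L = _tip_partials(tree, tip_states, states)
    up, _, P = _up_pass(tree, Q, L)
    maps = []
    for m in range(n_maps):
        rng = np.random.default_rng(None if seed is None
                                    else (int(seed) * 100_003 + m) % 2**31)
        node_state = np.empty(tree.n_nodes, dtype=int)
        root = tree.root
        w = up[root] * _root_weights(up[root], Q, root_prior)
        node_state[root] = rng.choice(len(states), p=w / w.sum())
        for nd in tree.preorder():
            for ch in tree.children[nd]:
                w = P[ch][node_state[nd], :] * up[ch]
                w = np.clip(w, 0, None)
                node_state[ch] = rng.choice(len(states), p=w / w.sum())
        segments = {}
        for nd in range(tree.n_nodes):
            if tree.parent[nd] < 0:
                continue
            segments[nd] = _sample_branch_history(
                Q, node_state[tree.parent[nd]], node_state[nd],
                tree.branch_lengths[nd], rng, states)
        rm = RegimeMap(tree, list(states), segments, node_state, map_id=m,
                       seed=seed)
        rm.validate()
        maps.append(rm)
    return maps
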