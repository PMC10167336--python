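"""Plotting utilities: ordination scatters, phylomorphospace, DTT."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordination_signal import OrdinationResult, phylomorphospace_coords
from .rates_disparity import DTTCurve

__all__ = ["plot_ordination", "plot_phylomorphospace", "plot_dtt"]


def plot_ordination(ord_result: OrdinationResult, groups=None, ax=None,
                    axes=(0, 1)):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    a, b = axes
    s = ord_result.scores
    if groups is None:
        ax.scatter(s[:, a], s[:, b], s=18)
    else:
        for g in sorted(set(groups)):
            m = [i for i, x in enumerate(groups) if x == g]
            ax.scatter(s[m, a], s[m, b], s=18, label=str(g))
        ax.legend(fontsize=8)
    pv = ord_result.percent_variance
    kind = ord_result.kind.upper()
    ax.set_xlabel(f"{kind}{a + 1} ({pv[a]:.1f}%)")
    ax.set_ylabel(f"{kind}{b + 1} ({pv[b]:.1f}%)")
    return ax


def plot_phylomorphospace(ord_result: OrdinationResult, tree, node_states,
                          groups=None, ax=None, axes=(0, 1)):
    """Tip scores with ancestral projections connected by tree edges."""
    ax = plot_ordination(ord_result, groups=groups, ax=ax, axes=axes)
    pm = phylomorphospace_coords(ord_result, tree, node_states)
    tips, nodes = pm["tip_scores"], pm["node_scores"]
    a, b = axes
    for pa, ch in pm["edges"]:
        x0, y0 = nodes[pa, a], nodes[pa, b]
        x1, y1 = nodes[ch, a], nodes[ch, b]
        ax.plot([x0, x1], [y0, y1], lw=0.5, color="0.6", zorder=0)
    return ax


def plot_dtt(curve: DTTCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.times, curve.envelope_lo, curve.envelope_hi,
                    alpha=0.25, color="0.6", label="95% BM envelope")
    ax.plot(curve.times, curve.sim_mean, "--", color="0.3", label="BM mean")
    ax.plot(curve.times, curve.observed, color="C3", label="observed")
    ax.set_xlabel("relative time")
    ax.set_ylabel("relative subclade disparity")
    ax.legend(fontsize=8)
    return ax
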