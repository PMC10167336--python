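"""Diet-guild construction and trophic-level categorisation.

Species are compared by the Bray-Curtis dissimilarity of their prey
proportion vectors, clustered with UPGMA (average linkage), and the
dendrogram is cut into k feeding guilds.  Species whose diet consists
of a single prey category can be excluded from clustering and labelled
by that category directly, mirroring the common practice of removing
monospecific diets before guild construction.  Trophic-level values
are binned into low-level (LP), meso- (MP) and top predators (TP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "GuildAssignment", "bray_curtis", "upgma", "assign_guilds",
    "trophic_category", "dendrogram_to_newick",
]

# trophic-level category bounds: TR <= 3.8 -> LP, 3.8 < TR <= 4.2 -> MP,
# TR > 4.2 -> TP.  The upper boundary's side is configurable because
# published usage is not consistent about where exactly 4.2 falls.
TR_BOUNDS = (3.8, 4.2)


@dataclass
class GuildAssignment:
    guilds: dict                    # species -> guild label
    linkage: np.ndarray             # scipy linkage matrix of clustered species
    clustered_species: list
    k: int
    excluded_monospecific: list


def bray_curtis(diet_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between species diet rows:
    ``D_ij = sum|x_i - x_j| / sum(x_i + x_j)``."""
    X = diet_matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("negative diet proportions")
    rowsum = X.sum(axis=1)
    if np.any(rowsum == 0):
        bad = list(diet_matrix.index[rowsum == 0])
        raise ValueError(f"all-zero diet rows for species {bad}")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    D = num / den
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=diet_matrix.index, columns=diet_matrix.index)


def upgma(distance: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration of a symmetric distance matrix;
    returns a scipy linkage matrix.  Deterministic: scipy breaks height
    ties by the lowest cluster index pair."""
    D = distance.to_numpy(dtype=float)
    if np.any(np.isnan(D)):
        raise ValueError("NaN distances")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def assign_guilds(diet_matrix: pd.DataFrame, k: int = 8,
                  exclude_monospecific: bool = False,
                  auto_k: bool = False) -> GuildAssignment:
    """Cut the UPGMA dendrogram of diet dissimilarities into k guilds.

    With ``exclude_monospecific``, species with a single nonzero prey
    category are removed before clustering and labelled by that sole
    category.  ``auto_k`` overrides k with the cut at the largest merge
    height gap.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mono, kept = [], []
    for sp in diet_matrix.index:
        row = diet_matrix.loc[sp].to_numpy(dtype=float)
        if exclude_monospecific and (row > 0).sum() == 1:
            mono.append(sp)
        else:
            kept.append(sp)
    sub = diet_matrix.loc[kept]
    if k > len(kept):
        raise ValueError(f"k={k} exceeds {len(kept)} clustered species")
    Z = upgma(bray_curtis(sub))
    if auto_k and len(kept) > 2:
        heights = Z[:, 2]
        gaps = np.diff(heights)
        k = len(kept) - (int(np.argmax(gaps)) + 1)
        k = max(k, 1)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    guilds = {sp: f"G{lab}" for sp, lab in zip(kept, labels)}
    for sp in mono:
        row = diet_matrix.loc[sp]
        guilds[sp] = str(row.index[np.argmax(row.to_numpy())])
    return GuildAssignment(guilds, Z, kept, int(k), mono)


def trophic_category(tr: float, boundary_open_upper: bool = False) -> str:
    """Bin a trophic-level value into LP / MP / TP.

    Default rule: ``TR <= 3.8 -> LP``, ``3.8 < TR <= 4.2 -> MP``,
    ``TR > 4.2 -> TP``.  With ``boundary_open_upper`` the value 4.2
    itself is classed TP instead (boundary cases are genuinely treated
    both ways in the literature).
    """
    tr = float(tr)
    if not np.isfinite(tr):
        raise ValueError("trophic level must be finite")
    if not (2.0 <= tr <= 5.5):
        warnings.warn(f"trophic level {tr} outside the plausible [2, 5.5]",
                      RuntimeWarning)
    lo, hi = TR_BOUNDS
    if tr <= lo:
        return "LP"
    if tr < hi or (tr == hi and not boundary_open_upper):
        return "MP"
    return "TP"


def dendrogram_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialise a linkage matrix as Newick with merge heights."""
    n = len(labels)
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    root = tree
    inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
    return f"({inner});"
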