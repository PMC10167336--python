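"""Generalized Procrustes analysis with sliding semilandmarks.

Alignment removes translation, scale and rotation (partial Procrustes:
configurations are kept at unit centroid size).  Semilandmarks slide to
minimise the thin-plate-spline bending energy of the deformation from
the current consensus: curve points along their local tangent, surface
points within their local tangent plane (Gunz-style relaxation).  No
projection back onto a mesh surface is performed — the pipeline works
from coordinates alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import LandmarkScheme, SpecimenTable

__all__ = [
    "centroid_size", "gpa", "slide_semilandmarks", "average_by_species",
    "AlignedSample", "SpeciesShapeMatrix", "optimal_rotation",
    "bending_energy_matrix", "bending_energy", "save_aligned_h5",
    "load_aligned_h5",
]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid.

    The standard geometric-morphometric size measure; scale-equivariant
    (``CS(c X) = c CS(X)``).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("config must be (p>=2, dim)")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    dev = config - config.mean(axis=0)
    return float(np.sqrt((dev ** 2).sum()))


def optimal_rotation(X: np.ndarray, ref: np.ndarray,
                     allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimising ``||X R - ref||``; reflections excluded by
    default (determinant forced to +1)."""
    U, _, Vt = np.linalg.svd(X.T @ ref)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


# --------------------------------------------------------------------- #
# thin-plate-spline bending energy
# --------------------------------------------------------------------- #
def bending_energy_matrix(reference: np.ndarray, reg: float = 0.0) -> np.ndarray:
    """Bending-energy matrix of the TPS interpolant anchored on
    ``reference`` (p x 3); 3-D kernel ``U(r) = r``.

    The returned symmetric PSD matrix ``Be`` gives the energy of a
    displacement field ``v`` (p per dimension) as ``sum_d v_d' Be v_d``.
    A singular anchor system (coincident points) is regularised with a
    warning.
    """
    X = np.asarray(reference, dtype=float)
    p = X.shape[0]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    K = d                      # 3-D TPS kernel
    Q = np.column_stack([np.ones(p), X])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = Q
    L[p:, :p] = Q.T
    if reg:
        L[:p, :p] += reg * np.eye(p)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        warnings.warn("singular bending-energy system; regularising",
                      RuntimeWarning)
        Linv = np.linalg.inv(L + 1e-8 * np.eye(p + 4))
    Be = Linv[:p, :p]
    Be = 0.5 * (Be + Be.T)
    # the 3-D kernel r yields -Be PSD on the nonaffine subspace; fix sign
    w = np.linalg.eigvalsh(Be)
    if w.sum() < 0:
        Be = -Be
    return Be


def bending_energy(Be: np.ndarray, displacement: np.ndarray) -> float:
    """Energy of a p x 3 displacement field under ``Be``."""
    v = np.asarray(displacement, dtype=float)
    return float(sum(v[:, k] @ Be @ v[:, k] for k in range(v.shape[1])))


# --------------------------------------------------------------------- #
# sliding
# --------------------------------------------------------------------- #
def _curve_tangents(config: np.ndarray, scheme: LandmarkScheme) -> dict:
    """Unit tangent per curve-interior landmark by central differences."""
    t = {}
    for curve in scheme.curves:
        for k in range(1, len(curve) - 1):
            i = curve[k]
            vec = config[curve[k + 1]] - config[curve[k - 1]]
            n = np.linalg.norm(vec)
            t[i] = vec / n if n > 0 else np.zeros(3)
    return t


def _surface_tangent_planes(consensus: np.ndarray,
                            scheme: LandmarkScheme, k: int = 6) -> dict:
    """Two leading principal directions of each surface landmark's ``k``
    nearest consensus neighbours."""
    planes = {}
    for i in scheme.surface_ids:
        d = np.linalg.norm(consensus - consensus[i], axis=1)
        nbr = np.argsort(d)[1:k + 1]
        cloud = consensus[nbr] - consensus[nbr].mean(axis=0)
        _, _, Vt = np.linalg.svd(cloud, full_matrices=False)
        planes[i] = (Vt[0], Vt[1])
    return planes


def slide_semilandmarks(configs: np.ndarray, consensus: np.ndarray,
                        scheme: LandmarkScheme) -> np.ndarray:
    """One sliding pass: move semilandmarks of every configuration to
    minimise TPS bending energy relative to the consensus.

    Curve points move along their tangent; surface points within their
    tangent plane; fixed landmarks are untouched.  The step is damped if
    a linearised solution would increase the energy, so the per-pass
    energy is non-increasing.
    """
    configs = np.asarray(configs, dtype=float).copy()
    single = configs.ndim == 2
    if single:
        configs = configs[None]
    p = scheme.p
    Be = bending_energy_matrix(consensus)
    planes = _surface_tangent_planes(consensus, scheme)
    E3 = np.kron(np.eye(3), Be)           # acts on [vx; vy; vz]

    for s in range(configs.shape[0]):
        X = configs[s]
        tangents = _curve_tangents(X, scheme)
        dirs, owners = [], []
        for i, t in tangents.items():
            dirs.append((i, t))
        for i, (u1, u2) in planes.items():
            dirs.append((i, u1))
            dirs.append((i, u2))
        m = len(dirs)
        if m == 0:
            continue
        U = np.zeros((3 * p, m))
        for col, (i, vec) in enumerate(dirs):
            for dim in range(3):
                U[dim * p + i, col] = vec[dim]
        v0 = (X - consensus).T.reshape(-1)          # [vx; vy; vz]
        A = U.T @ E3 @ U
        b = U.T @ E3 @ v0
        t_step = -np.linalg.solve(A + 1e-10 * np.trace(A) / m * np.eye(m), b)
        e0 = bending_energy(Be, X - consensus)
        step = 1.0
        for _ in range(30):
            Xn = X + (U @ (step * t_step)).reshape(3, p).T
            if bending_energy(Be, Xn - consensus) <= e0 + 1e-12:
                configs[s] = Xn
                break
            step *= 0.5
        # else: keep X unchanged (energy already minimal along dirs)
    return configs[0] if single else configs


# --------------------------------------------------------------------- #
# GPA
# --------------------------------------------------------------------- #
@dataclass
class AlignedSample:
    """Procrustes-aligned configurations with sizes and consensus."""

    specimen_ids: list
    species_ids: list
    aligned: np.ndarray               # (n, p, 3), unit centroid size
    centroid_sizes: np.ndarray        # original units
    consensus: np.ndarray             # (p, 3)
    scheme: LandmarkScheme
    iteration_log: list = field(default_factory=list)

    def flat(self) -> np.ndarray:
        """(n, 3p) matrix, landmark-major (x0 y0 z0 x1 ...)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def save_aligned_h5(sample: AlignedSample, path) -> None:
    """Write aligned coordinates, centroid sizes and consensus to HDF5."""
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("aligned", data=sample.aligned)
        fh.create_dataset("centroid_sizes", data=sample.centroid_sizes)
        fh.create_dataset("consensus", data=sample.consensus)
        ids = np.array(sample.specimen_ids, dtype=object)
        sp = np.array(sample.species_ids, dtype=object)
        dt = h5py.string_dtype()
        fh.create_dataset("specimen_ids", data=ids, dtype=dt)
        fh.create_dataset("species_ids", data=sp, dtype=dt)


def load_aligned_h5(path, scheme: LandmarkScheme) -> AlignedSample:
    import h5py
    with h5py.File(path, "r") as fh:
        return AlignedSample(
            [s.decode() for s in fh["specimen_ids"][()]],
            [s.decode() for s in fh["species_ids"][()]],
            fh["aligned"][()], fh["centroid_sizes"][()],
            fh["consensus"][()], scheme)


def _align_pass(configs, consensus, allow_reflection):
    out = np.empty_like(configs)
    for i, X in enumerate(configs):
        out[i] = X @ optimal_rotation(X, consensus, allow_reflection)
    return out


def gpa(specimens: SpecimenTable, slide: bool = True, max_iter: int = 100,
        tol: float = 1e-8, n_slide_passes: int = 3,
        allow_reflection: bool = False) -> AlignedSample:
    """Generalized Procrustes alignment of a specimen table.

    Interleaves semilandmark sliding passes with full re-alignment when
    ``slide`` is true.  The criterion (summed squared Procrustes
    distance to the consensus) is tracked per pass and is non-increasing
    until convergence at ``tol``.
    """
    n = len(specimens)
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    scheme = specimens.scheme
    raw = specimens.coords.astype(float)

    cs = np.empty(n)
    configs = np.empty_like(raw)
    for i in range(n):
        c = raw[i] - raw[i].mean(axis=0)
        size = centroid_size(raw[i])
        if size == 0 or np.linalg.matrix_rank(c) < 2:
            raise ValueError(
                f"degenerate configuration for specimen "
                f"{specimens.specimen_ids[i]}")
        cs[i] = size
        configs[i] = c / size

    log = []

    def _iterate(configs):
        consensus = configs[0].copy()
        prev = np.inf
        for it in range(max_iter):
            configs = _align_pass(configs, consensus, allow_reflection)
            consensus = configs.mean(axis=0)
            consensus -= consensus.mean(axis=0)
            csize = centroid_size(consensus)
            if csize > 0:
                consensus /= csize
            crit = float(((configs - consensus) ** 2).sum())
            log.append(crit)
            if abs(prev - crit) < tol:
                return configs, consensus, True
            prev = crit
        return configs, consensus, False

    configs, consensus, converged = _iterate(configs)
    if slide and (len(scheme.curve_interiors) or scheme.surface_ids):
        for _ in range(n_slide_passes):
            configs = slide_semilandmarks(configs, consensus, scheme)
            # sliding changes size/position slightly; re-normalise
            for i in range(n):
                configs[i] -= configs[i].mean(axis=0)
                configs[i] /= centroid_size(configs[i])
            configs, consensus, converged = _iterate(configs)
    if not converged:
        warnings.warn("GPA did not converge in max_iter; returning best "
                      "iterate", RuntimeWarning)
    return AlignedSample(list(specimens.specimen_ids),
                         list(specimens.species_ids), configs, cs,
                         consensus, scheme, log)


# --------------------------------------------------------------------- #
# species averaging
# --------------------------------------------------------------------- #
@dataclass
class SpeciesShapeMatrix:
    """Species x (3p) aligned coordinates averaged by species."""

    species: list
    matrix: np.ndarray                # (n_species, 3p)
    mean_log_cs: np.ndarray           # (n_species,)
    scheme: LandmarkScheme

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species)

    def coords(self) -> np.ndarray:
        return self.matrix.reshape(len(self.species), -1, 3)


def average_by_species(aligned: AlignedSample,
                       mapping: dict | None = None) -> SpeciesShapeMatrix:
    """Arithmetic per-species mean of aligned coordinates and of log CS.

    ``mapping`` overrides the specimen-to-species assignment recorded in
    the sample.  Single-specimen species pass through unchanged; sizes
    of zero raise a domain error at the log.
    """
    species_of = (mapping if mapping is not None
                  else dict(zip(aligned.specimen_ids, aligned.species_ids)))
    if np.any(aligned.centroid_sizes <= 0):
        raise ValueError("log centroid size undefined for CS <= 0")
    groups = {}
    for i, sid in enumerate(aligned.specimen_ids):
        groups.setdefault(species_of[sid], []).append(i)
    species = list(groups)
    flat = aligned.flat()
    mat = np.array([flat[groups[sp]].mean(axis=0) for sp in species])
    logcs = np.array([np.log(aligned.centroid_sizes[groups[sp]]).mean()
                      for sp in species])
    return SpeciesShapeMatrix(species, mat, logcs, aligned.scheme)
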