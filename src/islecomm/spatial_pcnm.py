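"""Spatial eigenvectors: PCNM basis and permutation forward selection.

Principal coordinates of neighbour matrices (PCNM) turn the island
geographic distance matrix into an orthogonal set of spatial variables
describing autocorrelation from broad to fine scales: distances above a
truncation threshold t (the longest minimum-spanning-tree edge, the
smallest value keeping the islands connected) are replaced by 4t, and
the positive-eigenvalue axes of the principal-coordinates decomposition
of the modified matrix form the basis.

Forward selection then keeps only the axes that add significant
constrained inertia in a CCA of the community, guarding against the
variance overestimation that using all axes would cause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .cca_partition import _chi_square_transform, _project, _weighted_design, _zero_negligible
from .core_io import OccurrenceMatrix
from .mantel import ProjectedCoordinates

__all__ = [
    "PCNMBasis",
    "truncation_threshold",
    "pcnm_basis",
    "forward_select",
    "ForwardSelectionStep",
]


@dataclass(frozen=True)
class PCNMBasis:
    """Positive-eigenvalue spatial axes ordered broad to fine scale."""

    island_ids: tuple[str, ...]
    eigenvectors: np.ndarray  # islands x axes, unit norm, centered
    eigenvalues: np.ndarray   # descending, all positive
    truncation_threshold: float

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


def truncation_threshold(coords: ProjectedCoordinates | np.ndarray) -> float:
    """Longest edge of the Euclidean minimum spanning tree of the islands.

    This is the smallest distance t such that linking every island pair
    closer than t leaves the archipelago connected — the classical PCNM
    truncation choice.  Duplicate points contribute zero-length edges and
    are harmless.
    """
    pts = coords.as_array() if isinstance(coords, ProjectedCoordinates) else \
        np.asarray(coords, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d = squareform(pdist(pts))
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


def pcnm_basis(coords: ProjectedCoordinates | np.ndarray,
               threshold: float | None = None,
               eig_tol: float = 1e-10) -> PCNMBasis:
    """PCNM decomposition of the truncated geographic distance matrix.

    Distances greater than ``threshold`` are replaced by 4 x threshold;
    the modified matrix undergoes a principal-coordinates decomposition
    (eigen-analysis of the double-centered -D²/2) and axes with
    eigenvalue > ``eig_tol`` x the largest eigenvalue are retained as
    unit-norm columns.

    ``threshold`` defaults to :func:`truncation_threshold`; passing a
    smaller value disconnects the island graph and draws a warning.
    """
    if isinstance(coords, ProjectedCoordinates):
        ids = coords.island_ids
        pts = coords.as_array()
    else:
        pts = np.asarray(coords, float)
        ids = tuple(str(i) for i in range(len(pts)))
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    t_min = truncation_threshold(pts)
    if threshold is None:
        threshold = t_min
    elif threshold < t_min - 1e-9:
        warnings.warn(f"threshold {threshold} below the connectivity "
                      f"threshold {t_min}; island graph is disconnected")
    d = squareform(pdist(pts))
    d = np.where(d > threshold, 4.0 * threshold, d)
    n = len(pts)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    keep = eigval > eig_tol * eigval[0]
    return PCNMBasis(island_ids=ids, eigenvectors=eigvec[:, keep],
                     eigenvalues=eigval[keep],
                     truncation_threshold=float(threshold))


@dataclass(frozen=True)
class ForwardSelectionStep:
    """One admitted axis: its index in the basis, added inertia, p-value."""

    axis: int
    added_inertia: float
    pseudo_f: float
    p: float


def forward_select(community: OccurrenceMatrix, candidates: PCNMBasis,
                   alpha: float = 0.05, n_perm: int = 999,
                   rng: np.random.Generator | None = None
                   ) -> list[ForwardSelectionStep]:
    """Two-stage permutation forward selection of spatial axes for a CCA.

    Stage 1 is a selection-aware gatekeeper: the best single-axis gain is
    compared against the permutation distribution of the *maximum* gain
    over all candidates.  If that test is not significant at ``alpha``
    the selection is empty — this is what keeps the type-I error of the
    whole procedure at the nominal level, since greedy best-of-many
    admission on its own is badly anticonservative, while a global
    all-candidates F-test dilutes signal concentrated on few axes.

    Stage 2 is the greedy walk: at each step the candidate adding the
    most constrained inertia given the already-selected axes is tested by
    a permutation pseudo-F (residuals of the reduced model permuted) and
    enters if p < alpha; selection stops at the first failure.  Ties
    break toward the lower axis index, so the procedure is deterministic
    given the generator state.

    Returns the admitted steps in selection order (possibly empty).
    """
    if candidates.n_axes == 0:
        raise ValueError("no candidate axes")
    if rng is None:
        rng = np.random.default_rng()
    y = community.values.T.astype(float)
    if y.sum() <= 0:
        raise ValueError("community has no presences")
    keep_sites = np.flatnonzero(y.sum(axis=1) > 0)
    axes = candidates.eigenvectors[keep_sites]
    yk = y[keep_sites]
    yk = yk[:, yk.sum(axis=0) > 0]
    q, r = _chi_square_transform(yk)
    total = float((q ** 2).sum())
    if total <= 1e-12:
        return []
    xw_all = _weighted_design(axes, r)
    n_sites = yk.shape[0]

    # stage 1: selection-aware gate — best single-axis gain against the
    # permutation distribution of the max gain over all candidates
    # (skipped when alpha >= 1: "admit every axis with positive gain")
    if alpha < 1.0:
        norms0 = np.linalg.norm(xw_all, axis=0)
        ok0 = norms0 > 0
        if not ok0.any():
            return []
        u0 = xw_all[:, ok0] / norms0[ok0]
        best0 = float(((u0.T @ q) ** 2).sum(axis=1).max())
        if best0 <= 1e-12:
            return []
        exceed = 0
        for _ in range(n_perm):
            perm_best = ((u0.T @ q[rng.permutation(n_sites)]) ** 2).sum(axis=1).max()
            if perm_best >= best0 - 1e-12:
                exceed += 1
        if (1 + exceed) / (n_perm + 1) >= alpha:
            return []

    # stage 2: greedy admission with per-step permutation pseudo-F
    selected: list[ForwardSelectionStep] = []
    chosen: list[int] = []
    remaining = list(range(candidates.n_axes))
    while remaining:
        zw = xw_all[:, chosen]
        fitted_z, rank_z = _project(zw, q)
        q_res = q - fitted_z
        conditioned = float((fitted_z ** 2).sum())
        # unit-norm residualized candidates: gain of axis a is the squared
        # projection of the residual community onto column a
        xr = _zero_negligible(
            xw_all[:, remaining] - _project(zw, xw_all[:, remaining])[0],
            xw_all[:, remaining])
        norms = np.linalg.norm(xr, axis=0)
        ok = norms > 0
        if not ok.any():
            break
        u = xr[:, ok] / norms[ok]
        live = [a for a, good in zip(remaining, ok) if good]
        gains = ((u.T @ q_res) ** 2).sum(axis=1)
        best_local = int(np.argmax(gains))
        best_gain = float(gains[best_local])
        if best_gain <= 1e-12:
            break
        best_axis = live[best_local]
        ub = u[:, best_local]
        df_resid = n_sites - 1 - rank_z - 1
        resid = total - conditioned - best_gain
        f_obs = best_gain / (resid / df_resid) if (df_resid > 0 and resid > 0) \
            else float("inf")
        exceed = 0
        for _ in range(n_perm):
            gain_p = float(((ub @ q_res[rng.permutation(n_sites)]) ** 2).sum())
            if gain_p >= best_gain - 1e-12:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        # alpha >= 1 means "admit every axis with positive added inertia"
        if p >= alpha and alpha < 1.0:
            break
        selected.append(ForwardSelectionStep(axis=best_axis,
                                             added_inertia=best_gain,
                                             pseudo_f=f_obs, p=p))
        chosen.append(best_axis)
        remaining.remove(best_axis)
    return selected
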