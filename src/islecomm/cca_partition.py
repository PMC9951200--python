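"""Canonical correspondence analysis, partial CCA, and variance partitioning.

Sites are islands and response variables are species presences; the
community table is analysed in the chi-square metric with island weights
proportional to island richness.  Rare species are NOT down-weighted.

The workhorse is :func:`cca`, which supports covariables (partial CCA):
constraints are residualized on the covariables in the row-weighted
space before the constrained fit, and the inertia absorbed by the
covariables is reported separately.  Variance partitioning between a
spatial and an environmental predictor set decomposes the explained
inertia into the two independent fractions plus a confounded (shared)
fraction, each as a percentage of total inertia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OccurrenceMatrix

__all__ = [
    "CCAResult",
    "PartitionResult",
    "cca",
    "permutation_test",
    "variance_partition",
    "isolation_partition",
    "ISOLATION_VARIABLES",
    "ENV_PARTITION_VARIABLES",
]

ISOLATION_VARIABLES = ("isw", "isd_m")

#: seven-variable environmental set for variance partitioning
ENV_PARTITION_VARIABLES = ("area_m2", "elevation_m", "sha", "veg_coverage",
                           "habitat_richness", "isw", "isd_m")

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class CCAResult:
    """Inertia accounting of a (partial) CCA fit."""

    total_inertia: float
    constrained_inertia: float
    conditioned_inertia: float
    residual_inertia: float
    eigenvalues: np.ndarray
    rank: int
    df_constraints: int
    df_covariables: int
    n_sites: int
    pseudo_f: float | None = None
    permutation_p: float | None = None

    @property
    def constrained_fraction(self) -> float:
        """Constrained inertia as a fraction of total inertia."""
        if self.total_inertia == 0:
            return 0.0
        return self.constrained_inertia / self.total_inertia


def _chi_square_transform(y: np.ndarray):
    """Double-centered chi-square residual matrix and row weights.

    Q[i,j] = (p_ij - r_i c_j) / sqrt(r_i c_j) with p = y / grand total.
    Total inertia is the sum of squared entries of Q.
    """
    f = y.sum()
    p = y / f
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    e = np.outer(r, c)
    q = (p - e) / np.sqrt(e)
    return q, r


def _weighted_design(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-weight a design matrix: weighted-center columns, scale by sqrt(r).

    Columns that are (numerically) constant vanish under centering and
    are zeroed exactly, so they contribute no rank downstream.
    """
    xc = x - (r @ x)  # weighted column means (sum r_i = 1)
    xw = np.sqrt(r)[:, None] * xc
    return _zero_negligible(xw, np.sqrt(r)[:, None] * x)


def _zero_negligible(w: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Zero columns of ``w`` that are negligible relative to ``ref``.

    Guards projections against columns that are exact-zero in principle
    (constant constraints after centering, duplicated sets after
    residualization) but ~1e-16 in floating point: without an absolute
    reference scale a QR rank filter would keep them and project onto
    pure rounding noise.
    """
    if w.size == 0:
        return w
    norms = np.linalg.norm(w, axis=0)
    refn = np.linalg.norm(ref, axis=0)
    out = w.copy()
    out[:, norms <= 1e-9 * (refn + 1e-300)] = 0.0
    return out


def _project(design: np.ndarray, target: np.ndarray):
    """Orthogonal projection of target onto col(design) via thin QR.

    Returns (fitted, rank).  Rank-deficient designs are handled by
    discarding negligible QR directions, so collinear constraints reduce
    the rank instead of failing.
    """
    if design.size == 0:
        return np.zeros_like(target), 0
    qmat, rmat = np.linalg.qr(design)
    diag = np.abs(np.diag(rmat))
    keep = diag > max(design.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    qmat = qmat[:, keep]
    return qmat @ (qmat.T @ target), int(keep.sum())


def _coerce_table(table, n_sites: int, keep_sites: np.ndarray) -> np.ndarray:
    if table is None:
        return np.empty((len(keep_sites), 0))
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(float)
    else:
        arr = np.asarray(table, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n_sites:
        raise ValueError(f"variable table has {arr.shape[0]} rows, "
                         f"expected {n_sites} islands")
    return arr[keep_sites]


def cca(community: OccurrenceMatrix | np.ndarray, constraints,
        covariables=None) -> CCAResult:
    """(Partial) canonical correspondence analysis.

    Parameters
    ----------
    community : OccurrenceMatrix or array
        Species x islands incidence (an array is taken as islands x
        species already).
    constraints : DataFrame or array, islands x p
        Explanatory variables whose effect is tested.
    covariables : DataFrame or array or None
        Variables to partial out before the constrained fit.

    Notes
    -----
    Inertia accounting: total = conditioned (covariables) + constrained
    (constraints after covariables) + residual.  Eigenvalues are those of
    the constrained part and sum to the constrained inertia.
    """
    if isinstance(community, OccurrenceMatrix):
        y = community.values.T.astype(float)
    else:
        y = np.asarray(community, float)
    if y.sum() <= 0:
        raise ValueError("community has no presences")
    n_all = y.shape[0]
    keep_sites = np.flatnonzero(y.sum(axis=1) > 0)
    if keep_sites.size < n_all:
        warnings.warn(f"dropping {n_all - keep_sites.size} empty island(s) "
                      "from the ordination")
    yk = y[keep_sites]
    yk = yk[:, yk.sum(axis=0) > 0]

    q, r = _chi_square_transform(yk)
    total = float((q ** 2).sum())

    x = _coerce_table(constraints, n_all, keep_sites)
    z = _coerce_table(covariables, n_all, keep_sites)
    xw = _weighted_design(x, r)
    zw = _weighted_design(z, r)

    fitted_z, rank_z = _project(zw, q)
    conditioned = float((fitted_z ** 2).sum())
    q_res = q - fitted_z
    xw_res = _zero_negligible(xw - _project(zw, xw)[0], xw)

    fitted, rank_x = _project(xw_res, q_res)
    constrained = float((fitted ** 2).sum())
    sv = np.linalg.svd(fitted, compute_uv=False) if fitted.size else np.array([])
    eig = sv ** 2
    eig = eig[eig > _EIG_TOL * (eig[0] if eig.size else 1.0)]

    residual = total - conditioned - constrained
    n_sites = yk.shape[0]
    df_resid = n_sites - rank_x - rank_z - 1
    pseudo_f = None
    if rank_x > 0 and df_resid > 0 and residual > 0:
        pseudo_f = (constrained / rank_x) / (residual / df_resid)
    return CCAResult(
        total_inertia=total, constrained_inertia=constrained,
        conditioned_inertia=conditioned, residual_inertia=residual,
        eigenvalues=eig, rank=len(eig), df_constraints=rank_x,
        df_covariables=rank_z, n_sites=n_sites, pseudo_f=pseudo_f,
    )


def permutation_test(community, constraints, covariables=None,
                     n_perm: int = 999,
                     rng: np.random.Generator | None = None):
    """Permutation pseudo-F test of the constrained inertia.

    F = (constrained / df_x) / (residual / df_resid).  When covariables
    are present the residuals of the reduced (covariables-only) model are
    permuted across islands, the standard scheme for partial constrained
    ordination; otherwise community rows are permuted directly.

    Returns ``(pseudo_F, p)``.
    """
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    if rng is None:
        rng = np.random.default_rng()

    if isinstance(community, OccurrenceMatrix):
        y = community.values.T.astype(float)
    else:
        y = np.asarray(community, float)
    n_all = y.shape[0]
    keep_sites = np.flatnonzero(y.sum(axis=1) > 0)
    yk = y[keep_sites]
    yk = yk[:, yk.sum(axis=0) > 0]
    q, r = _chi_square_transform(yk)
    total = float((q ** 2).sum())

    x = _coerce_table(constraints, n_all, keep_sites)
    z = _coerce_table(covariables, n_all, keep_sites)
    xw = _weighted_design(x, r)
    zw = _weighted_design(z, r)
    fitted_z, rank_z = _project(zw, q)
    q_res = q - fitted_z
    conditioned = float((fitted_z ** 2).sum())
    xw_res = _zero_negligible(xw - _project(zw, xw)[0], xw)

    n_sites = yk.shape[0]

    def stat(qr: np.ndarray):
        fitted, rank_x = _project(xw_res, qr)
        constrained = float((fitted ** 2).sum())
        df_resid = n_sites - rank_x - rank_z - 1
        residual = total - conditioned - constrained
        if rank_x == 0 or df_resid <= 0 or residual <= 0:
            return float("nan"), constrained
        return (constrained / rank_x) / (residual / df_resid), constrained

    f_obs, _ = stat(q_res)
    if np.isnan(f_obs):
        raise ValueError("pseudo-F undefined (saturated or inertia-free model)")
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_sites)
        f_perm, _ = stat(q_res[perm])
        if not np.isnan(f_perm) and f_perm >= f_obs - 1e-12:
            exceed += 1
    return float(f_obs), float((1 + exceed) / (n_perm + 1))


@dataclass(frozen=True)
class PartitionResult:
    """Two-set variance partition of community inertia, in percent.

    ``fraction_a`` — inertia explained by set 1 independently of set 2;
    ``fraction_c`` — set 2 independent of set 1; ``fraction_b`` — the
    confounded (shared) part, which may be negative; all relative to
    total inertia x 100.  a + b + c = total_explained.
    """

    fraction_a: float
    fraction_b: float
    fraction_c: float
    total_explained: float
    df_set1: int
    df_set2: int
    df_union: int
    p_a: float | None
    p_c: float | None
    n_sites: int

    def __post_init__(self) -> None:
        gap = self.fraction_a + self.fraction_b + self.fraction_c \
            - self.total_explained
        assert abs(gap) < 1e-6, f"partition accounting broken by {gap}"


def _hstack_tables(t1, t2) -> np.ndarray:
    a1 = t1.to_numpy(float) if isinstance(t1, pd.DataFrame) else np.asarray(t1, float)
    a2 = t2.to_numpy(float) if isinstance(t2, pd.DataFrame) else np.asarray(t2, float)
    if a1.ndim == 1:
        a1 = a1[:, None]
    if a2.ndim == 1:
        a2 = a2[:, None]
    return np.hstack([a1, a2])


def variance_partition(community, set1, set2, n_perm: int = 999,
                       rng: np.random.Generator | None = None
                       ) -> PartitionResult:
    """Partition community inertia between two explanatory variable sets.

    set1 is conventionally the spatial eigenvector set (dispersal
    signal), set2 the environmental variables (filtering signal).  The
    testable fractions a and c receive permutation p-values; the shared
    fraction b is obtained by difference and is not testable.
    """
    if rng is None:
        rng = np.random.default_rng()
    res_union = cca(community, _hstack_tables(set1, set2))
    res_a = cca(community, set1, covariables=set2)
    res_c = cca(community, set2, covariables=set1)
    total_in = res_union.total_inertia
    if total_in == 0:
        raise ValueError("community has zero total inertia")
    a = res_a.constrained_inertia / total_in * 100
    c = res_c.constrained_inertia / total_in * 100
    tot = res_union.constrained_inertia / total_in * 100
    b = tot - a - c
    p_a = p_c = None
    if n_perm > 0:
        # saturated partial models (rank of both sets + 1 >= n sites)
        # leave the pseudo-F undefined; the fractions are still reported
        try:
            _, p_a = permutation_test(community, set1, covariables=set2,
                                      n_perm=n_perm, rng=rng)
        except ValueError:
            p_a = None
        try:
            _, p_c = permutation_test(community, set2, covariables=set1,
                                      n_perm=n_perm, rng=rng)
        except ValueError:
            p_c = None
    return PartitionResult(
        fraction_a=a, fraction_b=b, fraction_c=c, total_explained=tot,
        df_set1=res_a.df_constraints, df_set2=res_c.df_constraints,
        df_union=res_union.df_constraints, p_a=p_a, p_c=p_c,
        n_sites=res_union.n_sites,
    )


def isolation_partition(community, islands: pd.DataFrame,
                        isolation_vars=ISOLATION_VARIABLES,
                        other_vars=None, n_perm: int = 999,
                        rng: np.random.Generator | None = None
                        ) -> PartitionResult:
    """Partition inertia into isolation-specific and confounded parts.

    set1 = the isolation attributes (water fraction ISW and shore
    distance ISD; df = 2), set2 = the remaining environmental variables,
    so ``fraction_a`` is the independent isolation effect,
    ``fraction_b`` the part confounded with the other variables, and
    ``total_explained`` the inertia explained by the full variable set.
    """
    if other_vars is None:
        other_vars = [v for v in ENV_PARTITION_VARIABLES
                      if v not in isolation_vars]
    missing = [v for v in (*isolation_vars, *other_vars)
               if v not in islands.columns]
    if missing:
        raise ValueError(f"island table lacks variables: {missing}")
    return variance_partition(community, islands[list(isolation_vars)],
                              islands[list(other_vars)], n_perm=n_perm,
                              rng=rng)
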