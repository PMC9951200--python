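"""Geographic / environmental distances and (partial) Mantel tests.

Distance construction follows the island-biogeography workflow: project
longitude/latitude to a local planar frame, take Euclidean distances for
geography, and Euclidean distances over z-score-standardized island
attributes for environmental divergence.  Significance of matrix
correlations is assessed by permuting island labels of the first matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .beta_null import ComparisonResult, DistanceMatrix, NullModelSpec, \
    compare_observed, mean_beta, null_distribution, pairwise_beta
from .core_io import OccurrenceMatrix

__all__ = [
    "ProjectedCoordinates",
    "MantelResult",
    "project_coordinates",
    "geographic_distance",
    "environmental_distance",
    "mantel",
    "partial_mantel",
    "null_expected_partial_mantel",
    "ENV_DISTANCE_VARIABLES",
]

EARTH_RADIUS_M = 6_371_000.0

#: default attribute set entering the environmental-divergence distance
ENV_DISTANCE_VARIABLES = ("area_m2", "elevation_m", "veg_coverage",
                          "habitat_richness")


@dataclass(frozen=True)
class ProjectedCoordinates:
    """Island positions in a local planar frame (metres)."""

    island_ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    reference: tuple[float, float]  # (lon, lat) of the projection origin

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class MantelResult:
    """Matrix correlation with permutation significance."""

    r: float
    p: float
    n_perm: int
    tail: str
    n_islands: int
    n_pairs: int


def project_coordinates(island_ids, lon, lat,
                        reference: tuple[float, float] | None = None
                        ) -> ProjectedCoordinates:
    """Equirectangular projection of lon/lat to local planar metres.

    x = R cos(lat_ref) Δlon, y = R Δlat (radians), R = 6,371,000 m.  At
    archipelago scales (tens of km) planar distances agree with
    great-circle distances to well under 0.1 %.

    ``reference`` defaults to the centroid of the input points.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if np.any(np.abs(lat) >= 90):
        raise ValueError("latitudes must lie strictly within (-90, 90)")
    if reference is None:
        reference = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = reference
    x = EARTH_RADIUS_M * np.cos(np.deg2rad(lat0)) * np.deg2rad(lon - lon0)
    y = EARTH_RADIUS_M * np.deg2rad(lat - lat0)
    return ProjectedCoordinates(tuple(str(i) for i in island_ids), x, y,
                                (lon0, lat0))


def geographic_distance(coords: ProjectedCoordinates) -> DistanceMatrix:
    """Planar Euclidean distance matrix over projected coordinates."""
    d = squareform(pdist(coords.as_array()))
    return DistanceMatrix(coords.island_ids, d)


def environmental_distance(islands: pd.DataFrame,
                           variables=ENV_DISTANCE_VARIABLES,
                           standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance over (standardized) island attributes.

    Columns are z-scored with the sample standard deviation by default so
    each attribute contributes on a common scale; zero-variance columns
    are dropped with a warning rather than producing 0/0.
    """
    missing_cols = [v for v in variables if v not in islands.columns]
    if missing_cols:
        raise ValueError(f"island table lacks variables: {missing_cols}")
    sub = islands[list(variables)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing attribute values for islands: {bad}")
    x = sub.to_numpy(float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [v for v, k in zip(variables, keep) if not k]
            warnings.warn(f"dropping zero-variance variables: {dropped}")
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    d = squareform(pdist(x))
    return DistanceMatrix(tuple(str(i) for i in islands.index), d)


def _aligned_condensed(*mats: DistanceMatrix) -> tuple[np.ndarray, ...]:
    ids = mats[0].island_ids
    for m in mats[1:]:
        if m.island_ids != ids:
            raise ValueError("distance matrices cover different island sets "
                             "or orders")
    vecs = [m.condensed() for m in mats]
    mask = np.ones_like(vecs[0], bool)
    for v in vecs:
        mask &= ~np.isnan(v)
    return tuple(v for v in vecs) + (mask,)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def _permuted_condensed(values: np.ndarray, perm: np.ndarray) -> np.ndarray:
    # relabel islands of a square matrix, return its condensed vector
    return squareform(values[np.ix_(perm, perm)], checks=False)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = (1 - rac ** 2) * (1 - rbc ** 2)
    if denom <= 0:
        raise ValueError("degenerate partial correlation: a controlling "
                         "correlation has |r| = 1")
    return (rab - rac * rbc) / np.sqrt(denom)


def _p_value(perm_stats: np.ndarray, observed: float, tail: str) -> float:
    if tail == "greater":
        exceed = np.sum(perm_stats >= observed - 1e-12)
    elif tail == "two-sided":
        exceed = np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + exceed) / (len(perm_stats) + 1))


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999,
           rng: np.random.Generator | None = None,
           tail: str = "greater") -> MantelResult:
    """Mantel test: Pearson correlation between two distance matrices.

    r is computed over the unmasked upper-triangle entries; significance
    comes from ``n_perm`` random relabelings of the islands of ``A``.
    The p-value uses the (1 + exceedances) / (n_perm + 1) convention and
    is never exactly zero.
    """
    if A.n < 3:
        raise ValueError("need at least 3 islands")
    if rng is None:
        rng = np.random.default_rng()
    va, vb, mask = _aligned_condensed(A, B)
    r_obs = _pearson(va[mask], vb[mask])
    perm_r = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(A.n)
        vap = _permuted_condensed(A.values, perm)
        m = mask & ~np.isnan(vap)
        perm_r[k] = _pearson(vap[m], vb[m])
    return MantelResult(r=r_obs, p=_p_value(perm_r, r_obs, tail),
                        n_perm=n_perm, tail=tail, n_islands=A.n,
                        n_pairs=int(mask.sum()))


def partial_mantel(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                   n_perm: int = 999, rng: np.random.Generator | None = None,
                   tail: str = "greater") -> MantelResult:
    """Partial Mantel test of A vs B controlling C.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC²)(1 - r_BC²)); the
    permutation scheme relabels the islands of ``A`` only and recomputes
    the partial statistic.  If ``C`` has zero variance over the defined
    pairs the statistic reduces to the simple Mantel r (r_AC = r_BC = 0).
    """
    if A.n < 3:
        raise ValueError("need at least 3 islands")
    if rng is None:
        rng = np.random.default_rng()
    va, vb, vc, mask = _aligned_condensed(A, B, C)
    vcm = vc[mask]
    degenerate_c = np.allclose(vcm, vcm.mean())

    def partial_stat(va_m, vb_m, vc_m):
        if degenerate_c:
            return _pearson(va_m, vb_m)
        return _partial_r(_pearson(va_m, vb_m), _pearson(va_m, vc_m),
                          _pearson(vb_m, vc_m))

    r_obs = partial_stat(va[mask], vb[mask], vcm)
    perm_r = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(A.n)
        vap = _permuted_condensed(A.values, perm)
        m = mask & ~np.isnan(vap)
        perm_r[k] = partial_stat(vap[m], vb[m], vc[m])
    return MantelResult(r=float(r_obs), p=_p_value(perm_r, r_obs, tail),
                        n_perm=n_perm, tail=tail, n_islands=A.n,
                        n_pairs=int(mask.sum()))


def null_expected_partial_mantel(matrix: OccurrenceMatrix,
                                 spec: NullModelSpec | str, n: int,
                                 geo: DistanceMatrix, env: DistanceMatrix,
                                 rng: np.random.Generator,
                                 observed_r: float | None = None
                                 ) -> tuple[np.ndarray, ComparisonResult]:
    """Null-model-expected partial Mantel correlations.

    For each of ``n`` randomized incidence matrices, recompute pairwise
    beta diversity and its partial correlation with geographic distance
    controlling environmental divergence.  The resulting distribution is
    compared with the observed partial r via a one-sample t-test.

    Replicates whose beta matrix leaves fewer than 3 defined pairs in
    common with geo/env are dropped (counted in the ensemble summary
    reported by :func:`islecomm.beta_null.null_distribution`).
    """

    def stat(m: OccurrenceMatrix) -> float:
        beta = pairwise_beta(m)
        try:
            va, vg, ve, mask = _aligned_condensed(beta, geo, env)
        except ValueError:
            return float("nan")
        if mask.sum() < 3:
            return float("nan")
        try:
            return _partial_r(_pearson(va[mask], vg[mask]),
                              _pearson(va[mask], ve[mask]),
                              _pearson(vg[mask], ve[mask]))
        except ValueError:
            return float("nan")

    if observed_r is None:
        observed_r = stat(matrix)
    values, _ens = null_distribution(matrix, spec, n, stat, rng)
    return values, compare_observed(observed_r, values)


def observed_mean_beta(matrix: OccurrenceMatrix) -> float:
    """Convenience: mean Jaccard beta over all defined island pairs."""
    return mean_beta(pairwise_beta(matrix))[0]
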