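"""Jaccard beta diversity and binary null models.

Pairwise Jaccard dissimilarity between island assemblages, six
randomization schemes for the species-by-island incidence matrix, and
observed-versus-expected comparisons.

Null-model naming: a two-letter code gives the constraint on species
(rows) then islands (columns) — E(quiprobable), P(roportional to the
observed margin), F(ixed margin).  The six schemes used here are EE, EF,
PE, PF, FE and FF.  All of them preserve the grand total of presences;
EF/PF/FF preserve island richness exactly and FE/FF preserve species
occurrence frequencies exactly.  FF samples uniformly from the set of
binary matrices with both margins fixed, via the curveball trade
algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import OccurrenceMatrix

__all__ = [
    "DistanceMatrix",
    "NullModelSpec",
    "NullEnsemble",
    "ComparisonResult",
    "NULL_MODELS",
    "jaccard_distance",
    "pairwise_beta",
    "mean_beta",
    "randomize",
    "null_distribution",
    "compare_observed",
    "compare_beta_between_taxa",
]

NULL_MODELS = ("EE", "EF", "PE", "PF", "FE", "FF")

_SCHEMES = {"E": "equip", "P": "prop", "F": "fixed"}


@dataclass(frozen=True)
class NullModelSpec:
    """One of the six row/column randomization schemes.

    ``code`` is the two-letter name; ``row_scheme``/``col_scheme`` spell
    out the constraint on species and islands respectively.
    """

    code: str

    def __post_init__(self) -> None:
        if self.code not in NULL_MODELS:
            raise ValueError(f"unknown null model {self.code!r}; "
                             f"expected one of {NULL_MODELS}")

    @property
    def row_scheme(self) -> str:
        return _SCHEMES[self.code[0]]

    @property
    def col_scheme(self) -> str:
        return _SCHEMES[self.code[1]]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity over islands with an undefined mask.

    ``values`` holds NaN where a pair is undefined (for Jaccard: both
    assemblages empty).  The diagonal is zero by construction.
    """

    island_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.island_ids),) * 2:
            raise ValueError("values shape does not match island_ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T), atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "island_ids", tuple(self.island_ids))

    @property
    def n(self) -> int:
        return len(self.island_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major order (NaN where undefined)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def defined_mask(self) -> np.ndarray:
        """Boolean mask over the condensed vector: True = pair defined."""
        return ~np.isnan(self.condensed())

    def n_undefined(self) -> int:
        return int(np.isnan(self.condensed()).sum())


def jaccard_distance(occ_i: np.ndarray, occ_j: np.ndarray) -> float:
    """Jaccard dissimilarity 1 - C/(A+B+C) between two binary vectors.

    C = shared presences, A/B = presences unique to either island.
    Returns NaN when both assemblages are empty (A+B+C = 0): the
    dissimilarity of two empty islands is undefined, not zero.
    """
    occ_i = np.asarray(occ_i)
    occ_j = np.asarray(occ_j)
    if occ_i.shape != occ_j.shape:
        raise ValueError("assemblage vectors differ in length")
    shared = int(np.sum((occ_i == 1) & (occ_j == 1)))
    union = int(np.sum((occ_i == 1) | (occ_j == 1)))
    if union == 0:
        return float("nan")
    return 1.0 - shared / union


def pairwise_beta(matrix: OccurrenceMatrix) -> DistanceMatrix:
    """All-pairs Jaccard dissimilarity between island assemblages.

    For n islands this yields n(n-1)/2 beta values.  A pair with exactly
    one empty island has beta 1; a pair of two empty islands is masked
    (NaN).
    """
    if matrix.n_islands < 2:
        raise ValueError("need at least 2 islands")
    m = matrix.values
    inter = (m.T.astype(np.int64) @ m).astype(float)
    totals = m.sum(axis=0).astype(float)
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(matrix.island_ids), d)


def mean_beta(d: DistanceMatrix) -> tuple[float, int]:
    """Arithmetic mean over defined island pairs.

    Returns ``(mean, n_masked)``.  When every pair is undefined (all
    randomized islands empty under a scheme that allows empty columns)
    the mean is NaN — the ``NA`` outcome some schemes produce on very
    sparse matrices.
    """
    vals = d.condensed()
    mask = ~np.isnan(vals)
    n_masked = int((~mask).sum())
    if not mask.any():
        return float("nan"), n_masked
    return float(vals[mask].mean()), n_masked


# ---------------------------------------------------------------------------
# randomization schemes


def _place_cells(shape, flat_idx) -> np.ndarray:
    out = np.zeros(shape, np.int8)
    out.ravel()[flat_idx] = 1
    return out


def _weighted_sample_without_replacement(weights: np.ndarray, k: int,
                                         rng: np.random.Generator) -> np.ndarray:
    """k indices sampled without replacement, P(i first) ∝ weights[i].

    Efraimidis–Spirakis exponential-key trick; zero-weight items are
    never drawn.
    """
    w = np.asarray(weights, float)
    pos = np.flatnonzero(w > 0)
    if k > pos.size:
        raise ValueError("fewer positive-weight items than draws")
    keys = rng.exponential(size=pos.size) / w[pos]
    return pos[np.argpartition(keys, k - 1)[:k]]


def _curveball_trades(presences: list[set[int]], n_trades: int,
                      rng: np.random.Generator) -> int:
    """In-place curveball trades on row presence sets; returns #effective."""
    n_rows = len(presences)
    effective = 0
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for r1, r2 in pairs:
        if r1 == r2:
            continue
        s1, s2 = presences[r1], presences[r2]
        only1 = s1 - s2
        only2 = s2 - s1
        n1 = len(only1)
        if n1 == 0 or len(only2) == 0:
            continue
        pool = np.fromiter(only1 | only2, int)
        rng.shuffle(pool)
        new1 = set(pool[:n1].tolist())
        if new1 != only1:
            effective += 1
        shared = s1 & s2
        presences[r1] = shared | new1
        presences[r2] = shared | set(pool[n1:].tolist())
    return effective


def _curveball_matrix(values: np.ndarray, n_trades: int,
                      rng: np.random.Generator) -> np.ndarray:
    presences = [set(np.flatnonzero(row).tolist()) for row in values]
    _curveball_trades(presences, n_trades, rng)
    out = np.zeros_like(values, np.int8)
    for i, s in enumerate(presences):
        out[i, list(s)] = 1
    return out


def randomize(matrix: OccurrenceMatrix, spec: NullModelSpec | str,
              rng: np.random.Generator) -> OccurrenceMatrix:
    """One randomized matrix under the given scheme.

    Scheme semantics (F = grand total of presences, always preserved):

    * ``EE`` — F presences placed uniformly at random among distinct cells.
    * ``FE`` — each species keeps its occurrence count; its islands are
      redrawn uniformly.
    * ``EF`` — each island keeps its richness; its species are redrawn
      uniformly.
    * ``PE`` — F distinct cells drawn with probability proportional to the
      observed occurrence frequency of the row, uniform over columns.
    * ``PF`` — each island keeps its richness, filled by sampling species
      without replacement with probability proportional to their observed
      occurrence frequencies.
    * ``FF`` — both margins preserved exactly; uniform sampling via
      curveball trades with a burn-in of 10 x n_species trades.
    """
    if isinstance(spec, str):
        spec = NullModelSpec(spec)
    m = matrix.values
    n_sp, n_is = m.shape
    total = int(m.sum())
    if total < 1:
        raise ValueError("matrix has no presences to randomize")
    row_tot = m.sum(axis=1)
    col_tot = m.sum(axis=0)
    code = spec.code

    if code == "EE":
        idx = rng.choice(n_sp * n_is, size=total, replace=False)
        out = _place_cells(m.shape, idx)
    elif code == "FE":
        out = np.zeros_like(m, np.int8)
        for i in range(n_sp):
            if row_tot[i]:
                out[i, rng.choice(n_is, size=row_tot[i], replace=False)] = 1
    elif code == "EF":
        out = np.zeros_like(m, np.int8)
        for j in range(n_is):
            if col_tot[j]:
                out[rng.choice(n_sp, size=col_tot[j], replace=False), j] = 1
    elif code == "PE":
        cell_w = np.repeat(row_tot.astype(float), n_is)
        idx = _weighted_sample_without_replacement(cell_w, total, rng)
        out = _place_cells(m.shape, idx)
    elif code == "PF":
        out = np.zeros_like(m, np.int8)
        w = row_tot.astype(float)
        for j in range(n_is):
            if col_tot[j]:
                out[_weighted_sample_without_replacement(w, col_tot[j], rng), j] = 1
    elif code == "FF":
        out = _curveball_matrix(m, 10 * max(n_sp, 1), rng)
    else:  # pragma: no cover
        raise AssertionError(code)
    return matrix.with_values(out)


@dataclass(frozen=True)
class NullEnsemble:
    """Summary of one randomization run (scheme, seed, replicate count)."""

    spec: NullModelSpec
    n: int
    seed: int | None
    n_undefined: int


def null_distribution(matrix: OccurrenceMatrix, spec: NullModelSpec | str,
                      n: int, statistic, rng: np.random.Generator,
                      seed: int | None = None):
    """Distribution of a plug-in statistic over n randomized matrices.

    ``statistic`` maps an :class:`OccurrenceMatrix` to a float (NaN for
    undefined, e.g. mean beta when every island pair is empty-empty).
    Undefined replicates are dropped and counted in the returned
    :class:`NullEnsemble`.

    For FF, a single curveball chain is used: burn-in of 10 x n_species
    trades, then one sample every max(n_species, n_islands) trades, so
    consecutive replicates are decorrelated draws from the fixed-margin
    set.

    Returns ``(values, ensemble)`` with ``values`` the defined statistic
    values.  ``spec`` may also be a callable ``(matrix, rng) -> matrix``
    implementing a custom randomizer.
    """
    if isinstance(spec, str):
        spec = NullModelSpec(spec)
    if n < 2:
        raise ValueError("need at least 2 randomizations")
    values = np.empty(n)
    if callable(spec) and not isinstance(spec, NullModelSpec):
        for k in range(n):
            values[k] = statistic(spec(matrix, rng))
        spec = None
    elif spec.code == "FF":
        presences = [set(np.flatnonzero(r).tolist()) for r in matrix.values]
        n_sp, n_is = matrix.values.shape
        _curveball_trades(presences, 10 * n_sp, rng)
        thin = max(n_sp, n_is)
        for k in range(n):
            _curveball_trades(presences, thin, rng)
            out = np.zeros_like(matrix.values, np.int8)
            for i, s in enumerate(presences):
                out[i, list(s)] = 1
            values[k] = statistic(matrix.with_values(out))
    else:
        for k in range(n):
            values[k] = statistic(randomize(matrix, spec, rng))
    defined = values[~np.isnan(values)]
    code = spec.code if isinstance(spec, NullModelSpec) else "custom"
    ens = NullEnsemble(spec=spec, n=n, seed=seed,
                       n_undefined=int(np.isnan(values).sum()))
    if defined.size == 0:
        raise ValueError(
            f"statistic undefined for all {n} replicates under {code} "
            "(every randomized matrix produced only empty-empty pairs)"
        )
    return defined, ens


# ---------------------------------------------------------------------------
# observed-vs-expected comparison


@dataclass(frozen=True)
class ComparisonResult:
    """Observed statistic versus its null distribution.

    The one-sample t-test treats the null values as the sample and the
    observed value as the reference mean, so df = n_valid - 1.  ``ses``
    is the standardized effect size (observed - null mean) / null sd.
    """

    observed: float
    expected_mean: float
    expected_sd: float
    t: float
    df: int
    p: float
    ses: float
    n_valid: int
    degenerate: bool = False


def compare_observed(observed: float, null_values) -> ComparisonResult:
    """One-sample t-test of a null distribution against the observed value."""
    nulls = np.asarray(null_values, float)
    nulls = nulls[~np.isnan(nulls)]
    if nulls.size < 2:
        raise ValueError("need at least 2 defined null values")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        equal = np.isclose(mean, observed)
        return ComparisonResult(
            observed=float(observed), expected_mean=mean, expected_sd=0.0,
            t=0.0 if equal else float("inf"), df=nulls.size - 1,
            p=1.0 if equal else 0.0, ses=float("nan"),
            n_valid=int(nulls.size), degenerate=True,
        )
    t, p = stats.ttest_1samp(nulls, popmean=observed)
    ses = (observed - mean) / sd
    return ComparisonResult(
        observed=float(observed), expected_mean=mean, expected_sd=sd,
        t=float(t), df=nulls.size - 1, p=float(p), ses=float(ses),
        n_valid=int(nulls.size),
    )


def compare_beta_between_taxa(d1: DistanceMatrix, d2: DistanceMatrix):
    """Welch two-sample t-test between the beta values of two taxa.

    Compares the defined pairwise dissimilarities of two taxon subsets
    (e.g. mosses vs liverworts).  Pair values from one archipelago are
    not independent observations; the test is the conventional screen,
    not a spatially corrected one.

    Returns ``(mean1, mean2, t, df, p)``.
    """
    v1 = d1.condensed()
    v1 = v1[~np.isnan(v1)]
    v2 = d2.condensed()
    v2 = v2[~np.isnan(v2)]
    if v1.size < 2 or v2.size < 2:
        raise ValueError("need at least 2 defined pairs in each matrix")
    res = stats.ttest_ind(v1, v2, equal_var=False)
    return (float(v1.mean()), float(v2.mean()), float(res.statistic),
            float(res.df), float(res.pvalue))
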