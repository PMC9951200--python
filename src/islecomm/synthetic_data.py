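"""Synthetic archipelagos and communities with known assembly regimes.

The generator builds a lake-island system — islands scattered in a
square lake, log-uniform areas, spatially autocorrelated environmental
attributes — and assembles binary communities from two tunable
processes:

* **dispersal limitation** — each species spreads from a source island
  with an exponential kernel ``exp(-d / lambda)``; ``lambda = inf``
  switches it off;
* **environmental filtering** — a Gaussian niche response
  ``exp(-(e - mu)^2 / (2 sigma^2))`` on a standardized environmental
  axis; ``sigma = inf`` switches it off;

plus a passive area effect ``(A / A_max)^w`` and a baseline occupancy
``q``, so the occurrence probability is

    p_ij = q * exp(-d(source_i, j)/lambda) * exp(-(e_j - mu_i)^2/(2 sigma_i^2)) * (A_j/A_max)^w

and presences are independent Bernoulli draws.  With all processes off
(lambda = sigma = inf, w = 0) cells are iid Bernoulli(q) — the neutral
reference every type-I-error check uses.

:func:`scenario_suite` bundles four named regimes (``dispersal_only``,
``environment_only``, ``mixed``, ``neutral``) used throughout the test
suite and the acceptance runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import OccurrenceMatrix
from .island_metrics import shape_irregularity
from .mantel import ProjectedCoordinates, project_coordinates

__all__ = [
    "ArchipelagoConfig",
    "CommunityConfig",
    "ScenarioBundle",
    "generate_archipelago",
    "generate_community",
    "generate_taxon_map",
    "scenario_suite",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("dispersal_only", "environment_only", "mixed", "neutral")

#: lon/lat of the synthetic lake centre (subtropical, arbitrary)
_REF_LON, _REF_LAT = 119.0, 29.5
_EARTH_R = 6_371_000.0


@dataclass(frozen=True)
class ArchipelagoConfig:
    """Geometry and environment of a synthetic lake-island system.

    ``extent_m`` is the side of the square lake; island areas are
    log-uniform in ``area_range_m2`` (default 0.25 ha to 100 ha, the
    size class of small land-bridge islands); environmental fields decay
    in spatial correlation over ``corr_range_m``.
    """

    n_islands: int = 60
    extent_m: float = 30_000.0
    area_range_m2: tuple[float, float] = (2_500.0, 1_000_000.0)
    corr_range_m: float = 6_000.0


@dataclass(frozen=True)
class CommunityConfig:
    """Per-regime assembly parameters (see module docstring)."""

    n_species: int = 200
    dispersal_scale_m: float = np.inf      # lambda; inf = no limitation
    niche_breadth: float = np.inf          # sigma on the standardized axis
    niche_axis: str = "elevation_m"
    baseline_occupancy: float = 0.5        # q
    area_exponent: float = 0.0             # w

    def __post_init__(self) -> None:
        if not (0 < self.baseline_occupancy <= 1):
            raise ValueError("baseline occupancy must be in (0, 1]")
        if self.dispersal_scale_m <= 0 or self.niche_breadth <= 0:
            raise ValueError("dispersal scale and niche breadth must be "
                             "positive (inf to disable)")


def _spatial_field(xy: np.ndarray, corr_range: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with exponential covariance."""
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d / corr_range) + 1e-8 * np.eye(len(xy))
    return np.linalg.cholesky(cov) @ rng.standard_normal(len(xy))


def generate_archipelago(config: ArchipelagoConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Generate an island attribute table (indexed by island_id).

    Coordinates are uniform in the lake square and reported as lon/lat
    about a fixed reference; areas log-uniform; elevation, habitat
    richness, vegetation coverage and shape irregularity ride on
    spatially autocorrelated Gaussian fields (habitat richness also
    grows with area, as larger islands hold more habitats); the shore
    distance ISD is the true distance to the lake boundary and the water
    fraction ISW shrinks with local island density.
    """
    if config.n_islands < 3:
        raise ValueError("need at least 3 islands")
    if config.extent_m <= 0:
        raise ValueError("degenerate extent")
    n = config.n_islands
    ext = config.extent_m
    xy = rng.uniform(0, ext, size=(n, 2))
    lo, hi = config.area_range_m2
    area = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    z_elev = _spatial_field(xy, config.corr_range_m, rng)
    z_hab = _spatial_field(xy, config.corr_range_m, rng)
    z_veg = _spatial_field(xy, config.corr_range_m, rng)
    z_sha = rng.standard_normal(n)

    log_rel_area = (np.log(area) - np.log(lo)) / (np.log(hi) - np.log(lo))
    elevation = 15.0 + 120.0 * log_rel_area + 40.0 * (z_elev - z_elev.min())
    habitat = np.maximum(
        1, np.rint(1 + 4 * log_rel_area + 1.2 * z_hab).astype(int))
    veg = np.clip(0.55 + 0.18 * z_veg, 0.05, 0.98)
    sha = 1.0 + np.abs(0.6 * z_sha)
    perimeter = sha * 2.0 * np.sqrt(area * np.pi)

    # isolation: shore distance = distance to the lake boundary; water
    # fraction rises with the gap to the nearest neighbouring island
    isd = np.minimum.reduce([xy[:, 0], xy[:, 1], ext - xy[:, 0],
                             ext - xy[:, 1]])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    isw = 1.0 / (1.0 + np.exp(-(nn - np.median(nn)) / (np.median(nn) + 1e-9)
                              - 0.3 * rng.standard_normal(n)))

    lat = _REF_LAT + np.rad2deg((xy[:, 1] - ext / 2) / _EARTH_R)
    lon = _REF_LON + np.rad2deg(
        (xy[:, 0] - ext / 2) / (_EARTH_R * np.cos(np.deg2rad(_REF_LAT))))

    df = pd.DataFrame({
        "lon": lon, "lat": lat, "area_m2": area, "elevation_m": elevation,
        "perimeter_m": perimeter, "habitat_richness": habitat,
        "veg_coverage": veg, "isw": np.clip(isw, 0.0, 1.0), "isd_m": isd,
        "sha": sha,
    }, index=pd.Index([f"isl{i + 1:03d}" for i in range(n)],
                      name="island_id"))
    # consistency: the stored SHA is exactly the perimeter/area index
    assert np.allclose(
        [shape_irregularity(p, a) for p, a in zip(perimeter, area)], sha)
    return df


def island_coordinates(islands: pd.DataFrame) -> ProjectedCoordinates:
    """Projected planar coordinates of a (synthetic or read) island table."""
    return project_coordinates(islands.index, islands["lon"], islands["lat"])


def generate_community(islands: pd.DataFrame, config: CommunityConfig,
                       rng: np.random.Generator) -> OccurrenceMatrix:
    """Assemble a binary species-by-island matrix under the given regime."""
    coords = island_coordinates(islands)
    xy = coords.as_array()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    n_is = len(islands)
    n_sp = config.n_species

    axis = islands[config.niche_axis].to_numpy(float)
    e = (axis - axis.mean()) / axis.std(ddof=1)
    area = islands["area_m2"].to_numpy(float)
    area_factor = (area / area.max()) ** config.area_exponent

    sources = rng.integers(0, n_is, size=n_sp)
    mu = rng.uniform(e.min(), e.max(), size=n_sp)

    p = np.full((n_sp, n_is), config.baseline_occupancy)
    if np.isfinite(config.dispersal_scale_m):
        p *= np.exp(-d[sources] / config.dispersal_scale_m)
    if np.isfinite(config.niche_breadth):
        p *= np.exp(-(e[None, :] - mu[:, None]) ** 2
                    / (2.0 * config.niche_breadth ** 2))
    p *= area_factor[None, :]
    cells = (rng.random((n_sp, n_is)) < p).astype(np.int8)
    return OccurrenceMatrix(pd.DataFrame(
        cells,
        index=[f"sp{i + 1:03d}" for i in range(n_sp)],
        columns=islands.index,
    ))


def generate_taxon_map(species_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Random but structurally valid taxon map for synthetic species.

    Divisions follow a bryophyte-like mix (~2/3 mosses, ~1/3 liverworts,
    rare hornworts); mosses split evenly between acrocarpous and
    pleurocarpous growth forms; families are drawn from a small pool per
    division so family subsets are non-trivial.
    """
    species_ids = list(species_ids)
    division = rng.choice(["moss", "liverwort", "hornwort"],
                          size=len(species_ids), p=[0.66, 0.32, 0.02])
    moss_fams = [f"MossFam{i}" for i in range(1, 7)]
    liver_fams = [f"LiverFam{i}" for i in range(1, 4)]
    rows = []
    for sp, div in zip(species_ids, division):
        if div == "moss":
            gf = rng.choice(["acrocarpous", "pleurocarpous"])
            fam = rng.choice(moss_fams)
        elif div == "liverwort":
            gf, fam = "not_applicable", rng.choice(liver_fams)
        else:
            gf, fam = "not_applicable", "HornFam1"
        rows.append({"species_id": sp, "family": fam, "division": div,
                     "growth_form": gf})
    return pd.DataFrame(rows).set_index("species_id")


@dataclass(frozen=True)
class ScenarioBundle:
    """One named assembly regime: islands + community + taxa + parameters."""

    name: str
    islands: pd.DataFrame = field(repr=False)
    matrix: OccurrenceMatrix = field(repr=False)
    taxa: pd.DataFrame = field(repr=False)
    archipelago_config: ArchipelagoConfig
    community_config: CommunityConfig


_BASE_ARCH = ArchipelagoConfig()

_SCENARIO_COMMUNITIES = {
    # lambda = extent / 10 when dispersal acts; sigma = 0.7 standardized
    # units when filtering acts; a mild passive area effect accompanies
    # filtering regimes
    "dispersal_only": CommunityConfig(dispersal_scale_m=_BASE_ARCH.extent_m / 10,
                                      baseline_occupancy=0.8),
    "environment_only": CommunityConfig(niche_breadth=0.7,
                                        baseline_occupancy=0.6,
                                        area_exponent=0.2),
    # mixed uses gentler versions of both processes so neither signal
    # drives occupancy to zero when they multiply
    "mixed": CommunityConfig(dispersal_scale_m=_BASE_ARCH.extent_m / 5,
                             niche_breadth=1.0, baseline_occupancy=0.8,
                             area_exponent=0.2),
    "neutral": CommunityConfig(baseline_occupancy=0.3),
}


def scenario_suite(seed: int = 0,
                   n_islands: int | None = None,
                   n_species: int | None = None
                   ) -> dict[str, ScenarioBundle]:
    """The four named regimes, each fully reproducible from the seed.

    All four share one archipelago geometry family (fresh draw per
    scenario from the seeded stream) so differences between regimes come
    from the assembly process, not the map.
    """
    out = {}
    for name in SCENARIO_NAMES:
        rng = np.random.default_rng([seed, SCENARIO_NAMES.index(name)])
        arch = _BASE_ARCH if n_islands is None else \
            replace(_BASE_ARCH, n_islands=n_islands)
        comm = _SCENARIO_COMMUNITIES[name]
        if n_species is not None:
            comm = replace(comm, n_species=n_species)
        islands = generate_archipelago(arch, rng)
        matrix = generate_community(islands, comm, rng)
        taxa = generate_taxon_map(matrix.species_ids, rng)
        out[name] = ScenarioBundle(name=name, islands=islands, matrix=matrix,
                                   taxa=taxa, archipelago_config=arch,
                                   community_config=comm)
    return out
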