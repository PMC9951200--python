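"""End-to-end orchestration: from input tables to the six result tables.

``run_pipeline`` reads (or receives) an occurrence matrix, island table
and taxon map, then produces TSV analogues of the standard island
community-assembly result set:

* table1 — observed vs null-expected mean beta diversity per taxon category
* table2 — the same per family
* table3 — partial Mantel tests (beta vs geography | environment) with
  null-model-expected partial correlations
* table4 — variance partitioning, spatial eigenvectors vs environment
* table5 — isolation-specific variance partitioning
* table6 — species-area relationships (optionally with published rows)

plus a JSON run manifest (seed, parameters, warnings) sufficient to
reproduce every table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta_null import NULL_MODELS, compare_observed, mean_beta, \
    null_distribution, pairwise_beta
from .cca_partition import ENV_PARTITION_VARIABLES, isolation_partition, \
    variance_partition
from .core_io import TAXON_CATEGORIES, OccurrenceMatrix, read_island_table, \
    read_occurrence_matrix, read_taxon_map, subset_taxon, validate_bundle
from .island_metrics import shape_irregularity
from .mantel import ENV_DISTANCE_VARIABLES, environmental_distance, \
    geographic_distance, null_expected_partial_mantel, partial_mantel
from .sar import compare_z, fit_sar
from .spatial_pcnm import forward_select, pcnm_basis
from .synthetic_data import island_coordinates

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("beta_categories", "beta_families", "mantel", "pcnm",
           "varpart", "isolation", "sar")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    matrix_path: str
    islands_path: str
    taxa_path: str
    out_dir: str
    selectors: tuple[str, ...] = TAXON_CATEGORIES
    null_models: tuple[str, ...] = NULL_MODELS
    n_randomizations: int = 1000
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    min_family_species: int = 5
    published_sar_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_randomizations < 2:
            raise ValueError("n_randomizations must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for p in (self.matrix_path, self.islands_path, self.taxa_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("selectors", "null_models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    # independent stream per stage so re-ordering stages cannot change results
    return np.random.default_rng([seed, _STAGES.index(stage)])


def _ensure_sha(islands: pd.DataFrame) -> pd.DataFrame:
    if "sha" not in islands.columns:
        islands = islands.copy()
        islands["sha"] = [
            shape_irregularity(p, a)
            for p, a in zip(islands["perimeter_m"], islands["area_m2"])
        ]
    return islands


def _beta_table(matrix: OccurrenceMatrix, taxa: pd.DataFrame, selectors,
                models, n_rand: int, seed: int, stage: str) -> pd.DataFrame:
    rows = []
    for sel in selectors:
        sub = subset_taxon(matrix, taxa, sel)
        observed, _ = mean_beta(pairwise_beta(sub))
        row: dict = {"taxon": sel, "observed": observed}
        for model in models:
            rng = _stage_rng(seed, stage)
            try:
                values, ens = null_distribution(
                    sub, model, n_rand,
                    lambda m: mean_beta(pairwise_beta(m))[0], rng)
                cmp_res = compare_observed(observed, values)
                row.update({
                    f"{model}_mean": cmp_res.expected_mean,
                    f"{model}_sd": cmp_res.expected_sd,
                    f"{model}_t": cmp_res.t, f"{model}_p": cmp_res.p,
                    f"{model}_ses": cmp_res.ses,
                    f"{model}_n_valid": cmp_res.n_valid,
                })
            except ValueError:
                # every replicate undefined (all pairs empty-empty): NA
                row.update({f"{model}_{k}": float("nan")
                            for k in ("mean", "sd", "t", "p", "ses")})
                row[f"{model}_n_valid"] = 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write table1..table6 + manifest to out_dir.

    Returns a mapping of logical table names to written paths.  Any
    stage failure aborts with a message naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    matrix = read_occurrence_matrix(config.matrix_path)
    islands = _ensure_sha(read_island_table(config.islands_path))
    taxa = read_taxon_map(config.taxa_path)
    issues = validate_bundle(matrix, islands, taxa)
    islands = islands.loc[matrix.island_ids]

    coords = island_coordinates(islands)
    geo = geographic_distance(coords)
    env = environmental_distance(islands, ENV_DISTANCE_VARIABLES)

    outputs: dict[str, Path] = {}

    def write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t")
        outputs[name] = path

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        stage = "beta_categories"
        try:
            write("table1", _beta_table(matrix, taxa, config.selectors,
                                        config.null_models,
                                        config.n_randomizations,
                                        config.seed, stage))
            stage = "beta_families"
            fam_counts = taxa.loc[
                [s for s in matrix.species_ids if s in taxa.index],
                "family"].value_counts()
            families = [f for f, c in fam_counts.items()
                        if c >= config.min_family_species]
            write("table2", _beta_table(matrix, taxa, families,
                                        config.null_models,
                                        config.n_randomizations,
                                        config.seed, stage))

            stage = "mantel"
            rows = []
            for sel in config.selectors:
                sub = subset_taxon(matrix, taxa, sel)
                beta = pairwise_beta(sub)
                rng = _stage_rng(config.seed, stage)
                obs = partial_mantel(beta, geo, env,
                                     n_perm=config.n_permutations, rng=rng)
                row = {"taxon": sel, "observed_r": obs.r, "observed_p": obs.p}
                for model in config.null_models:
                    rng = _stage_rng(config.seed, stage)
                    try:
                        _, cmp_res = null_expected_partial_mantel(
                            sub, model, config.n_randomizations, geo, env,
                            rng, observed_r=obs.r)
                        row.update({f"{model}_mean_r": cmp_res.expected_mean,
                                    f"{model}_t": cmp_res.t,
                                    f"{model}_p": cmp_res.p})
                    except ValueError:
                        row.update({f"{model}_{k}": float("nan")
                                    for k in ("mean_r", "t", "p")})
                rows.append(row)
            write("table3", pd.DataFrame(rows).set_index("taxon"))

            stage = "pcnm"
            basis = pcnm_basis(coords)
            rng = _stage_rng(config.seed, stage)
            steps = forward_select(matrix, basis, alpha=config.alpha,
                                   n_perm=config.n_permutations, rng=rng)
            sel_axes = [s.axis for s in steps]
            pcnm_frame = pd.DataFrame(
                basis.eigenvectors,
                index=list(basis.island_ids),
                columns=[f"PCNM{i + 1}" for i in range(basis.n_axes)])
            pcnm_frame.index.name = "island_id"
            write("pcnm_axes", pcnm_frame)
            write("pcnm_selection", pd.DataFrame(
                [{"axis": f"PCNM{s.axis + 1}", "added_inertia": s.added_inertia,
                  "pseudo_F": s.pseudo_f, "p": s.p} for s in steps]))

            stage = "varpart"
            env_vars = [v for v in ENV_PARTITION_VARIABLES
                        if v in islands.columns]
            # fall back to the broadest-scale axis when selection is empty,
            # and cap the spatial set so the partial model is not saturated
            axes_used = sel_axes or [0]
            cap = max(1, matrix.n_islands - len(env_vars) - 2)
            spatial = basis.eigenvectors[:, axes_used[:cap]]
            rows = []
            for sel in config.selectors:
                sub = subset_taxon(matrix, taxa, sel)
                rng = _stage_rng(config.seed, stage)
                part = variance_partition(sub, spatial, islands[env_vars],
                                          n_perm=config.n_permutations,
                                          rng=rng)
                rows.append({
                    "taxon": sel, "spatial_pct": part.fraction_a,
                    "spatial_df": part.df_set1, "spatial_p": part.p_a,
                    "env_pct": part.fraction_c, "env_df": part.df_set2,
                    "env_p": part.p_c, "confounded_pct": part.fraction_b,
                    "total_pct": part.total_explained,
                })
            write("table4", pd.DataFrame(rows).set_index("taxon"))

            stage = "isolation"
            rows = []
            for sel in config.selectors:
                sub = subset_taxon(matrix, taxa, sel)
                rng = _stage_rng(config.seed, stage)
                part = isolation_partition(sub, islands,
                                           n_perm=config.n_permutations,
                                           rng=rng)
                rows.append({
                    "taxon": sel,
                    "isolation_pct": part.fraction_a,
                    "isolation_df": part.df_set1, "isolation_p": part.p_a,
                    "confounded_pct": part.fraction_b,
                    "total_pct": part.total_explained,
                    "total_df": part.df_union,
                })
            write("table5", pd.DataFrame(rows).set_index("taxon"))

            stage = "sar"
            areas = islands["area_m2"]
            fits = {}
            for sel in config.selectors:
                sub = subset_taxon(matrix, taxa, sel)
                fits[sel] = fit_sar(areas.to_numpy(),
                                    sub.richness().to_numpy())
            published = None
            if config.published_sar_path:
                published = pd.read_csv(config.published_sar_path,
                                        index_col=0)
            write("table6", compare_z(fits, published))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        caught = [str(w.message) for w in wlist]

    manifest = {
        "islecomm_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "validation_issues": issues,
        "warnings": caught,
        "n_species": matrix.n_species,
        "n_islands": matrix.n_islands,
        "pcnm_axes_total": int(basis.n_axes),
        "pcnm_axes_selected": len(sel_axes),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    outputs["manifest"] = manifest_path
    return outputs
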