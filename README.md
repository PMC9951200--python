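# islecomm

Tools for asking a classic island-biogeography question of binary
species-by-island data: **how much of community assembly is dispersal
limitation, and how much is environmental filtering?**

On land-bridge archipelagos (reservoir islands, forest fragments),
species composition varies island to island. Two processes compete to
explain that variation: a stochastic spatial one — propagules simply do
not reach far islands — and a deterministic niche-based one — islands
filter arrivals by area, elevation, habitat, vegetation. `islecomm`
implements the full inference chain used to separate the two:

1. **Beta diversity vs null models.** Pairwise Jaccard dissimilarity
   `JD = 1 − C/(A+B+C)` between island assemblages, with the observed
   mean compared against expectations from six binary null models
   (EE, EF, PE, PF, FE, FF — species/island margins Equiprobable,
   Proportional or Fixed; FF sampled uniformly by curveball trades),
   via one-sample *t*-tests and standardized effect sizes
   `SES = (obs − mean_null)/sd_null`.
2. **Partial Mantel tests.** Correlation of beta diversity with
   geographic distance controlling environmental divergence
   (`r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²))`), permutation
   significance, and null-model-calibrated expected partial
   correlations.
3. **PCNM + partial CCA variance partitioning.** Spatial eigenvectors
   (principal coordinates of the truncated neighbour matrix) selected by
   a two-stage permutation forward selection, then canonical
   correspondence analysis partitioning compositional inertia into
   fractions explained independently by space (dispersal signal),
   independently by environment (filtering signal), and confounded
   between them — including an isolation-specific partition (water
   fraction ISW, shore distance ISD).
4. **Species-area relationships.** `ln(S+1) = C + z·ln(A)` fits, with
   *z*-value ranking across taxa and published biotas.
5. **Island metrics.** Shape irregularity `SHA = P/(2√(Aπ))`,
   raster-based ISW, and sampling-adequacy checks from specimen
   accumulation curves (Clench asymptote, `SE = (E−O)/E·100`).
6. **A synthetic archipelago generator** with known assembly regimes
   (`dispersal_only`, `environment_only`, `mixed`, `neutral`) so the
   whole chain is testable end to end with known truth:
   `p_ij = q · e^{−d(src_i,j)/λ} · e^{−(e_j−μ_i)²/2σ²} · (A_j/A_max)^w`.

Intended users: community ecologists and biogeographers with
presence/absence matrices from island-like systems, and methodologists
who want a seeded, fully scripted version of this analysis stack.

## Worked example

Analyse a synthetic dispersal-limited archipelago (60 islands, 200
species, exponential kernel λ = 3 km on a 30 km lake):

```python
import numpy as np
from islecomm import (scenario_suite, pairwise_beta, mean_beta,
                      null_distribution, compare_observed, partial_mantel,
                      geographic_distance, environmental_distance,
                      pcnm_basis, forward_select, variance_partition, fit_sar)
from islecomm.synthetic_data import island_coordinates
from islecomm.cca_partition import ENV_PARTITION_VARIABLES

bundle = scenario_suite(seed=7)["dispersal_only"]
matrix, islands = bundle.matrix, bundle.islands

obs, _ = mean_beta(pairwise_beta(matrix))
values, _ = null_distribution(matrix, "FF", 1000,
                              lambda m: mean_beta(pairwise_beta(m))[0],
                              np.random.default_rng(7))
cmp = compare_observed(obs, values)

coords = island_coordinates(islands)
geo, env = geographic_distance(coords), environmental_distance(islands)
pm = partial_mantel(pairwise_beta(matrix), geo, env, n_perm=999,
                    rng=np.random.default_rng(7))

basis = pcnm_basis(coords)
steps = forward_select(matrix, basis, alpha=0.05, n_perm=999,
                       rng=np.random.default_rng(7))
part = variance_partition(matrix,
                          basis.eigenvectors[:, [s.axis for s in steps]],
                          islands[list(ENV_PARTITION_VARIABLES)],
                          n_perm=999, rng=np.random.default_rng(7))
fit = fit_sar(islands["area_m2"].to_numpy(), matrix.richness().to_numpy())
```

Formatted with f-strings, those results print as:

```
community: 200 species x 60 islands, fill 0.046
observed mean Jaccard beta: 0.9763 (0 undefined pairs)
FF null: expected 0.9774 +/- 0.0002, t = 150.0, p = 0, SES = -4.74
partial Mantel (beta ~ geography | environment): r = 0.5368, p = 0.001
PCNM: 36 positive axes, 35 selected
variance partition: spatial 61.37% (p=0.001), environmental 8.99% (p=0.001), shared 6.87%, total 77.24%
SAR: z = -0.0084, C = 2.3588, r = -0.039
```

Reading it: mean beta sits significantly *below* the fixed-margin (FF)
expectation — near islands share species, so turnover is less than
margins alone predict; the partial Mantel finds strong distance decay
after controlling environment (r = 0.54); variance partitioning
attributes 61% of compositional inertia independently to space versus
9% to environment — the fingerprint of dispersal limitation, which is
exactly how this regime was simulated; and the flat SAR (z ≈ 0) is
correct for this scenario, which has no area effect built in.

## Command line

```sh
islecomm simulate --scenario mixed --seed 7 --out demo/        # matrix/islands/taxa CSVs
islecomm nullbeta --matrix demo/matrix.csv --taxa demo/taxa.csv \
    --models EE,EF,PE,PF,FE,FF --n 1000 --seed 42 --out table1.tsv
islecomm sar --matrix demo/matrix.csv --islands demo/islands.csv \
    --taxa demo/taxa.csv --out table6.tsv
islecomm run --config run.yaml       # full pipeline: tables 1-6 + manifest
```

`run.yaml` fields: `matrix_path`, `islands_path`, `taxa_path`,
`out_dir`, and optionally `selectors`, `null_models`,
`n_randomizations`, `n_permutations`, `alpha`, `seed`,
`min_family_species`, `published_sar_path`. The run manifest
(`manifest.json`) echoes every parameter and seed, and re-running the
same config reproduces every table byte for byte.

## File formats

- occurrence matrix: CSV/TSV, header = island ids, first column =
  species id, cells 0/1 (orientation flag for islands-as-rows files);
- `islands.csv`: `island_id,lon,lat,area_m2,elevation_m,perimeter_m,habitat_richness,veg_coverage,isw,isd_m`;
- `taxa.csv`: `species_id,family,division,growth_form` with division in
  {moss, liverwort, hornwort} and growth form in
  {acrocarpous, pleurocarpous, not_applicable}.

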