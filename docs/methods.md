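# Methods

This note documents the statistical machinery in `islecomm`: the models
and their assumptions, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
decisions that matter for reproducibility.

## Beta diversity and null models

Beta diversity between two islands is the Jaccard dissimilarity
`JD = 1 − C/(A+B+C)` on presences (C shared, A and B unique to either
island). A pair with exactly one empty assemblage has `JD = 1`; a pair
of two empty assemblages is *undefined* and is masked, not imputed as 0
or 1 — means are taken over defined pairs only and the masked count is
reported. This matters because several null models (notably EE) can
empty islands on sparse matrices, and propagating the undefined state
honestly reproduces the "no valid values" outcome such schemes produce
on species-poor taxon subsets.

The six randomization schemes are named by their constraint on species
rows then island columns — E(quiprobable), P(roportional to the
observed margin), F(ixed margin):

- **EE** — all F presences placed uniformly over distinct cells;
- **FE / EF** — each row (column) keeps its total, placed uniformly
  over columns (rows);
- **PE** — distinct cells drawn with probability ∝ species occurrence
  frequency, uniform over islands (Efraimidis–Spirakis weighted
  sampling without replacement);
- **PF** — island richness fixed, species drawn without replacement
  ∝ occurrence frequency;
- **FF** — both margins fixed exactly, sampled by curveball trades.

All schemes preserve the grand total of presences. FF uses a burn-in of
10 × n_species trades; `null_distribution` runs one chain with thinning
of max(n_species, n_islands) trades between samples, while standalone
`randomize` calls re-burn-in from the observed matrix so single draws
are independent. Uniformity of the FF sampler over the fixed-margin set
is verified in the tests against exhaustive enumeration on small
matrices (chi-square goodness of fit over 10,000 draws).

Observed-vs-expected comparison treats the null values as the sample of
a one-sample *t*-test with the observed value as reference
(df = n_valid − 1), plus `SES = (obs − mean)/sd`. The default number of
randomizations is 1000 and is configurable. Between-taxon comparisons
of beta-value distributions use Welch's *t* on the defined pair values;
pair values from one archipelago are not independent observations, so
this is the conventional screen, not a spatially corrected test.

## Distances and (partial) Mantel tests

Coordinates are projected equirectangularly about the archipelago
centroid (x = R cos(lat₀)Δlon, y = R Δlat, R = 6,371 km). At a 30 km
extent this agrees with great-circle distances to ≈0.1% on average
(worst pairs ≈0.12%, from the cos-latitude variation across the box)
and preserves distance ordering exactly, which is what matrix
correlations consume. Environmental divergence is Euclidean distance
over z-scored attributes (default set: area, elevation, vegetation
coverage, habitat richness); zero-variance columns are dropped with a
warning.

The Mantel statistic is the Pearson correlation over defined
upper-triangle entries; the partial version is the first-order partial
correlation of the three matrix correlations. Significance permutes the
island labels of the first matrix only (the community matrix),
recomputing the partial statistic each time; p-values follow the
`(1 + exceedances)/(n_perm + 1)` convention and can never be exactly 0.
The default tail is one-sided "greater", matching the directional
distance-decay hypothesis; two-sided is a flag. If the controlling
matrix has zero variance over the defined pairs the partial statistic
reduces to the simple Mantel r (logged, not an error). Null-calibrated
expected partial correlations re-run beta → partial-r on each
randomized matrix and compare to the observed r as above.

## PCNM and forward selection

The spatial basis is the classical PCNM construction: truncate the
geographic distance matrix at t = the longest minimum-spanning-tree
edge (the smallest t keeping the island graph connected), replace
larger distances by 4t, double-center −D²/2, and keep eigenvectors with
eigenvalue > 1e-10 × the largest. Columns are unit-norm, centered, and
ordered broad → fine scale. Negative-eigenvalue (repulsion) axes are
out of scope.

Forward selection is two-stage:

1. **Gate.** The best single-axis constrained inertia is compared with
   the permutation distribution of the *maximum* single-axis inertia
   over all candidates. This is selection-aware — under a community
   independent of space it rejects at exactly the nominal rate — and it
   is more powerful than a global all-candidates F-test when signal
   concentrates on few axes (a global F spreads one axis's signal over
   the full candidate df). If the gate fails, the selection is empty.
2. **Greedy walk.** The candidate adding the most constrained inertia
   given the already-selected axes enters if its permutation pseudo-F
   (reduced-model residuals permuted) has p < α; selection stops at the
   first failure. Ties break toward the lower axis index, so the result
   is deterministic given the generator state.

Without the gate, step-wise admission alone is badly anticonservative
(best-of-k selection bias: ~25% false selections at α = 0.05 with ~10
candidates in our simulations); with it, the false-selection rate over
independent communities is at the nominal level. `alpha >= 1` bypasses
the gate and admits every axis with positive added inertia, which is
occasionally useful for diagnostics. A known power limitation: when
spatial signal is weak *per axis* (very sparse matrices, gentle
kernels), the gate can return an empty selection even though aggregated
statistics (partial Mantel on beta) detect the pattern — constrained
ordination on sparse binary data is noisier than distance-based
aggregation. The pipeline then falls back to the broadest-scale axis so
downstream partitions remain defined, and reports the selected count in
its manifest.

## CCA, partial CCA, and variance partitioning

Sites are islands, responses are species presences, analysed in the
chi-square metric: with p = Y/F, row weights r and column weights c,
the working matrix is Q = (p − rcᵀ)/√(rcᵀ) and total inertia is ΣQ².
Rare species are **not** down-weighted. Constraints are weighted-centered
and scaled by √r; the constrained inertia is the squared norm of the QR
projection of Q onto that design, and the constrained eigenvalues come
from the SVD of the fitted part. Covariables (partial CCA) are
projected out of both Q and the constraints first, and the inertia they
absorb is reported as conditioned. Empty islands have zero chi-square
weight and are dropped with a warning (their count is logged);
all-zero species columns carry no inertia and are dropped silently.

Numerical guards: collinear constraints reduce the reported rank
instead of erroring (QR pivot filter), and columns that are zero *in
principle* — constant constraints after centering, duplicated sets
after residualization — are zeroed exactly against a reference scale
before projection, because a purely relative rank filter would
otherwise project onto rounding noise. The engine's inertia accounting
is oracle-tested against an independent brute-force implementation
(explicit loops, pseudo-inverses, dense eigendecompositions) to 1e-10.

Permutation tests use pseudo-F = (constrained/df_x)/(residual/df_res),
permuting reduced-model residuals when covariables are present. A
saturated partial model (ranks + 1 ≥ n sites) leaves the pseudo-F
undefined; partitions still report their fractions with p = None.

Variance partitioning between a spatial set S and environmental set E:
a = inertia(S | E), c = inertia(E | S), total = inertia(S ∪ E), and the
confounded fraction b = total − a − c (which may be negative), all as
percentages of total inertia; a + b + c = total is asserted to 1e-6.
The isolation-specific partition uses set1 = {ISW, ISD} (df = 2)
against the remaining five environmental variables, with the full
seven-variable set {area, elevation, SHA, vegetation coverage, habitat
richness, ISW, ISD} as the default environmental pool.

## Species-area relationships

`ln(S+1) = C + z ln(A)`, area in m², by ordinary least squares; the +1
retains zero-richness islands. r is the Pearson correlation of the
transformed variables, so r² is the regression's coefficient of
determination; z is invariant to area-unit changes (only C shifts) and
to the logarithm base as long as both sides share it. `compare_z` ranks
fitted taxa alongside externally supplied published (C, z, r) rows,
passed through unchanged.

## Island metrics

- `SHA = P/(2√(Aπ))`: 1 for a circle, scale-invariant, larger = more
  irregular shoreline.
- ISW: water fraction within a circle of 500 m *diameter* centred on
  the island, computed on a 0/1 raster by cell-center inclusion; for
  real coastlines users supply precomputed values in the island table
  (polygon GIS is out of scope). The circle is centred on the island
  centroid for synthetic data; the choice of interior point is
  otherwise the user's.
- Sampling adequacy: specimen order is randomized (default 100
  orderings), the mean accumulation curve is fit with the Clench
  (Michaelis–Menten) form S(n) = an/(1+bn) — chosen as the standard
  asymptotic model for specimen-based accumulation — and the asymptote
  E = a/b yields `SE = (E−O)/E·100`. Fits whose asymptote undershoots
  the observed richness are flagged rather than clamped: a near-linear
  curve means the extrapolation is unreliable.

## Synthetic archipelagos

`generate_archipelago` scatters islands uniformly in a square lake
(default 60 islands, 30 km side), draws areas log-uniform between
0.25 ha and 100 ha (the size class of small land-bridge islands), and
builds environmental attributes on Gaussian random fields with
exponential spatial covariance (range 6 km), so environment is
spatially autocorrelated — as in real archipelagos, and deliberately
so: it makes the space-vs-environment confounding the partitioning must
untangle actually present. Habitat richness additionally grows with
area; shore distance ISD is the true distance to the lake boundary;
ISW rises with the gap to the nearest neighbouring island; perimeter is
derived from the drawn shape index so SHA is exactly consistent.

`generate_community` assembles each species from a source island with

p_ij = q · exp(−d(src_i, j)/λ) · exp(−(e_j − μ_i)²/(2σ_i²)) · (A_j/A_max)^w

and independent Bernoulli draws; λ = ∞ disables dispersal limitation,
σ = ∞ disables filtering, and with both off and w = 0 cells are iid
Bernoulli(q) — the neutral reference for type-I checks. The dispersal
kernel is exponential: real spore kernels are argued to be fat-tailed,
and this choice is a deliberate simplification (one scale parameter,
easy to reason about); the niche axis is standardized elevation by
default, one axis only.

Scenario defaults (fixed once, used by tests and recovery runs):

| scenario | λ | σ | q | w |
|---|---|---|---|---|
| dispersal_only | extent/10 = 3 km | ∞ | 0.8 | 0 |
| environment_only | ∞ | 0.7 | 0.6 | 0.2 |
| mixed | extent/5 = 6 km | 1.0 | 0.8 | 0.2 |
| neutral | ∞ | ∞ | 0.3 | 0 |

q is high in dispersal regimes so occupancy is arrival-limited rather
than establishment-limited; `mixed` uses gentler kernels than the pure
regimes because the two suppression factors multiply and would
otherwise drive occupancy toward zero. With these settings the pure
regimes are cleanly attributed by the pipeline (spatial fraction
dominates under dispersal_only, environmental under environment_only,
each in ≳90% of replicates at these sizes), which is what the
acceptance tests assert.

What the generator does *not* emulate: colonization–extinction
dynamics through time, interspecific interactions, fat-tailed
dispersal, multi-axis niches, observation error in the inventories, and
phylogenetic structure in the taxon map (families are assigned at
random). Passing the recovery tests therefore shows the chain detects
and attributes the two processes it models, under spatially
autocorrelated environments — not that it is robust to every process
shaping real island floras.

## Problem sizes and seeds

Simulation-based checks run at 40–60 islands and 100–200 species with
199 Mantel permutations and 99 forward-selection permutations per
replicate (200 replicates for type-I calibration, 100 for power) —
sizes at which the permutation machinery is exercised end to end while
a full suite run stays in tens of seconds. All randomness flows through
explicitly passed numpy Generators; the pipeline expands one user seed
into independent per-stage streams, so stage reordering cannot change
results, and its manifest (seed, parameters, versions, warnings)
suffices to regenerate every output table byte for byte.

## Known limitations

- Pair-level values feeding the *t*-tests and Welch comparisons are
  non-independent (each island contributes to n−1 pairs); this follows
  the conventional procedure rather than correcting it.
- The FF chain's thinning is heuristic; for pathological margin sets
  (near-frozen matrices) consecutive samples can stay correlated. The
  trade counter in the sampler and the enumeration-based uniformity
  test bound this risk only at small sizes.
- Partial CCA p-values via reduced-model residual permutation are
  approximate when row weights are very uneven (rich vs empty-ish
  islands).
- The equirectangular projection is inappropriate beyond ~100 km
  extents or near the poles.
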