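# Methods

## Statistical model

All regressions are phylogenetic generalized least squares under the
Pagel-λ covariance model. Given a rooted tree with branch lengths, the
Brownian covariance `C` has `C[i, j]` equal to the shared root-to-MRCA path
length of tips *i* and *j* and `C[i, i]` equal to the depth of tip *i*. The
λ transform multiplies the off-diagonal entries by λ ∈ [0, 1]:
`V(λ) = λC + (1−λ)·diag(C)`, interpolating between phylogenetic
independence and full Brownian covariance. For a design matrix X and
response y the error covariance is σ²V(λ); β and σ² are profiled
analytically at each λ and λ is maximised by bounded scalar optimisation
(Brent on [0, 1], `xatol = 1e-8`), with the boundary values λ = 0 and λ = 1
checked explicitly so the reported optimum always dominates both. The fit
is ML (not REML) throughout; AIC counts λ and σ² in k (k = p + 2), the
phylolm-style convention. Standard errors use the unbiased residual
variance RSS_V/(n−p); p-values are two-tailed t with n−p df.

Numerical route: ultrametric trees (constant tip depth T) admit
`V(λ) = U·diag(λw + (1−λ)T)·Uᵀ` for the eigendecomposition `C = U·diag(w)·Uᵀ`,
so one symmetric eigendecomposition per tree serves every λ and every model
on that tree — each profile evaluation is O(n·p²) after rotating X and y
once. Non-ultrametric trees (accepted; diagonals are the actual tip depths,
no normalisation) use a Cholesky factorisation per λ. The two routes agree
to 1e-8 in the test suite, and the profiled likelihood is checked against a
direct multivariate-normal density.

R² for a model is `1 − RSS_V(model)/RSS_V(null)`, each residual sum of
squares whitened by its own fitted V, clipped to [0, 1], with the
intercept-only model (re-fit with its own ML λ) as the default null; a
likelihood-based pseudo-R² is available behind `r2_method="loglik"`. The
intercept-only baseline (rather than the allometric null) is the default
because the reported appendage-model R² values are "variance explained"
statements; both baselines can be computed by passing the desired null to
`r_squared`.

"Phylogenetic residuals" are raw-scale residuals y − Xβ̂ (not V-whitened):
downstream models re-estimate phylogenetic covariance themselves, so
whitening here would double-count tree structure. They satisfy
XᵀV⁻¹e = 0 at the fitted λ.

## Phylogenetic signal and PCA

Pagel's λ for a single trait is the ML λ of the intercept-only model; the
reported p-value is a likelihood-ratio test of λ̂ against λ = 0 on χ²(1)
(the statistic is floored at 0 since λ̂ is boundary-constrained). The
phylogenetic PCA centres traits on their GLS (ancestral) means and
eigendecomposes the phylogeny-weighted covariance
`(X − 1a)ᵀ C⁻¹ (X − 1a)/(n − 1)`; scores are projections of the centred
traits. On a star tree this reduces exactly to ordinary PCA. In the PCA
scaling of body shape, PC1 (computed from standardized log mass, beak and
tarsus) is body size; the mapping of PC2/PC3 to beak- and tarsus-shape axes
is this package's convention and is recorded in the output metadata.

## Climate metrics

Polygons flagged anything other than extant + native + a known season
(breeding, winter, year_round) are excluded; species losing every polygon
land in an exclusion report rather than raising. Remaining polygons are
unioned per species × season. Zonal means use pixel-centre containment,
unweighted over included pixels, with an all-touched fallback for sliver
polygons whose interiors cover no pixel centre; a geometry covering only
nodata raises. The five metrics are computed over season sets — warm
(breeding ∪ year_round) for max-of-months Tmax and Tavg, cold
(winter ∪ year_round) for min-of-months Tmin and Tavg, and all ranges for
the annual Tavg mean. A species missing a required season set gets a
missing metric with a logged reason rather than a substituted season:
substituting (say) year-round ranges for missing winter ranges would bias
the cold-season extremes.

Range area is taken on the Eckert IV equal-area projection (implemented
directly: Newton iteration on θ + sinθcosθ + 2sinθ = (2 + π/2)sinφ, sphere
of authalic radius 6 371 007.18 m) after densifying polygon edges to 0.25°;
a spherical-excess geodesic computation serves as the independent oracle in
tests (agreement within 0.5 %). Planar/synthetic CRSs report native-CRS
area. Raster stacks are stored as plain 12-band arrays on a north-up affine
grid; file I/O is multiband TIFF plus a JSON sidecar with the grid
geometry, CRS and nodata value.

Left-skewed temperature responses can be transformed by
`reflect_log(x) = −ln(max(x) + ε − x)` with ε = 0.5 °C by default (strictly
increasing; ε keeps the maximum finite) or by normal scores of mid-ranks;
the method and its parameters are recorded in provenance metadata.

## Model ladders

The Bergmann family is {intercept-only, |latitude|, one model per climate
metric} for log mass; the Allen families extend the allometric null
(`log length ~ log mass`) by |latitude|, by each single metric, and by each
metric crossed with log mass (one metric per model — the metrics are
tightly correlated). The temperature family runs from the intercept-only
model through all subsets of {body size, relative beak, relative tarsus}
and all combinations of their two-way interactions up to the full-factorial
three-way model. The builders accept any number of climate columns. All
candidates in a set are fit on the intersection of complete cases so AICs
are comparable; AIC ties below 1e-6 go to the model with fewer parameters,
then input order. Controls (migratory habit, log range area) enter every
candidate as additive fixed effects; migratory habit is treatment-coded
with resident as the reference level. Continuous covariates are uncentred
by default (a `center` flag is provided).

## Path analysis

Candidate causal models are the four DAGs in each response framing:
allometry only; + Bergmann; + Allen; mixed. The d-separation basis set has
one claim per non-adjacent vertex pair, conditioned on the union of both
vertices' parents; the regression child is the causally downstream member
(or the later vertex in topological order when neither is an ancestor) —
the convention of standard phylogenetic path-analysis tooling. Each claim's
p-value is the two-tailed PGLS p of the independent variable given the
conditioning set, on variables standardized to mean 0 and SD 1 so the path
coefficients are comparable effect sizes. Fisher's C = −2Σln p with 2k df;
p-values of exactly 0 are clamped at 1e-300 with a warning. Models are
ranked by the small-sample CICc = C + 2qn/(n−1−q) (plain C + 2q behind a
flag), with q = number of edges + number of vertices with parents
(intercepts); q is reported alongside results so alternative conventions
can be diffed. Multi-tree robustness refits per tree and reports
coefficient quantiles; AICs and CICs are never averaged across trees.

A structural caveat: when the true model is nested inside a larger
candidate that only adds edges absorbing true independence claims (the
Bergmann-vs-mixed contest), the expected CICc difference is near zero —
dropping two true claims reduces C by ≈ 4 in expectation while the penalty
grows by ≈ 4. Selection between such neighbours is then close to a coin
flip weighted ~60/40 toward the sparser truth; this is a property of the
criterion, not of the implementation.

## Synthetic data generator

The generator emulates the statistical structure of the global avian
dataset the method targets, not its biogeography.

* **Trees**: pure-birth (Yule) with all tips extant, hence ultrametric;
  default birth rate 1 per lineage (tree depth then grows like Σ1/k, about
  `ln n`; the analyses are invariant to overall depth scaling).
* **Traits**: generated in topological order of a chosen causal DAG.
  Exogenous traits are λ-model draws (covariance normalised to unit tip
  variance so `noise_sd` is the marginal SD). Allometric edges use the
  fitted global avian coefficients — log beak = 1.4345 + 0.3362 log mass,
  log tarsus = 2.1141 + 0.2883 log mass (natural logs, mm vs g) — on raw
  log mass; all other edges add coefficient × mean-centred parent, and
  `"a*b"` coefficient keys add product (interaction) terms.
* **Calibration**: log mass is centred on the avian median of 35.5 g with
  marginal SD 1.8 (masses span roughly 0.1 g–100 kg across communities);
  appendage residual SDs (0.39 beak, 0.34 tarsus) put the allometric R²
  near 72–73 %; the Bergmann coefficient (−0.07 log-mass per °C against a
  temperature SD of 8 °C) puts temperature's share of mass variance near
  10 %; Allen effects are +0.012 (beak) and −0.008 (tarsus, the inverse
  pattern seen in birds). λ defaults are 0.9 for temperature and mass, 0.8
  for appendages. Migratory habits are drawn (0.6, 0.25, 0.15) for
  resident/partial/full — a resident-majority split chosen once as
  realistic.
* **Worlds**: monthly Tavg is an equator-to-pole linear gradient
  (28 °C − 0.55 °C/deg·|lat|) plus a hemisphere-phased seasonal cosine
  (amplitude 15 °C·|lat|/90, northern peak in July) plus iid pixel noise
  (SD 0.3 °C); Tmin/Tmax are ∓6 °C offsets, so the per-pixel ordering
  holds by construction. Ranges are buffered circles placed at the
  latitude whose annual-mean field equals the species' generated
  temperature; migrants get poleward breeding and equatorward winter
  blobs. The truth table stores the pipeline's own metrics computed on the
  noise-free fields, so extraction error reflects only pixelization and
  noise. Synthetic worlds use a planar degree grid (no geodesy); the
  Eckert IV path is exercised by the geodesic-oracle tests instead.
* **Determinism**: one root seed spawns independent, stage-named
  sub-streams (CRC-derived), so identical (scenario, seed) reproduce
  byte-identical outputs and stages can be regenerated independently.

What passing tests on these worlds do **not** show: robustness to real
biogeography (ragged range shapes, antimeridian crossings, coastline
nodata), to non-ultrametric or miscalibrated trees beyond the Cholesky
route, to measurement error in traits, or to climate-trait confounding
structures outside the four candidate DAGs.

## Problem sizes

The shipped test suite and acceptance script use 200–500-tip communities,
20–200 replicates per experiment and 48×96–100×100 raster grids — sizes
chosen so the full validation runs in about a minute on one CPU while
keeping Monte-Carlo errors well below the effect sizes being recovered.

## Known limitations

* No OU or early-burst covariance kernels, measurement-error models, or
  mixed models (out of scope by design).
* CICc near-equivalence of nested causal neighbours (see above).
* The reflect-log skew transform's ε and the PCA axis-to-shape mapping are
  package conventions, recorded in output metadata.
* Antimeridian-crossing ranges are not repaired; within-period temporal
  trends and microclimate are not modelled.
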