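# ecorules

Joint phylogenetic tests of **Bergmann's rule** (body size decreases toward
warm climates) and **Allen's rule** (relative appendage length increases
toward warm climates) across a species-level phylogeny, built for avian-style
comparative datasets: a trait table (body mass, beak length, tarsus length,
migratory habit), monthly temperature rasters, seasonal range polygons, and
one or many phylogenetic trees.

The package is aimed at comparative biologists who want the full analysis
chain — species-range climate extraction, allometric scaling, phylogenetic
regression, AIC model ladders and causal path analysis — as composable,
tested Python, with a synthetic-data generator that makes every stage
verifiable end to end without any external downloads.

## The models

**PGLS under the Pagel-λ model.** Trait regressions are generalized least
squares with error covariance σ²·V(λ), where V(λ) multiplies the
off-diagonal entries of the Brownian-motion phylogenetic covariance *C*
(shared root-to-MRCA path lengths) by λ ∈ [0, 1]:

  β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y,  V(λ) = λ·C + (1−λ)·diag(C)

λ, σ² and β are estimated jointly by maximum likelihood (λ profiled on
[0, 1]); AIC = −2ℓ + 2k with k counting the coefficients plus λ and σ².
Candidate ladders are ranked by AIC with the conventional support classes
(ΔAIC < 2 most likely, < 7 somewhat likely).

**Allometry and relative appendage size.** The allometric null model is the
log–log PGLS `log length ~ log mass`; its raw phylogenetic residuals are the
primary "relative beak/tarsus length". An appendage scales isometrically
with a volumetric mass at exponent 1/3. Log length/mass ratios and
phylogenetic-PCA axes are provided as parallel scalings.

**Climate metrics.** Five per-species temperatures from 12-layer monthly
stacks and seasonal ranges: max temperature of all months and average
temperature of the hottest month (Tmax/Tavg over breeding ∪ year-round
ranges), minimum temperature of all months and average temperature of the
coldest month (Tmin/Tavg over winter ∪ year-round), and the all-months Tavg
mean over all ranges — plus centroid |latitude| and the Eckert IV
(equal-area) range size.

**Phylogenetic path analysis.** Four causal DAGs over {temperature,
log mass, log beak, log tarsus} — allometry only, + Bergmann, + Allen, and
the mixed model — are scored by the d-separation basis set: each
non-adjacent pair yields a PGLS conditional-independence test, Fisher's
C = −2Σln p ~ χ²(2k) under the correct model, and models are ranked by
CICc = C + 2qn/(n−1−q).

## Worked example

```python
from ecorules import (SyntheticScenario, candidate_dags, fit_paths,
                      rank_paths, simulate_traits, simulate_tree)

scenario = SyntheticScenario(n_tips=500, causal_model="mixed", seed=4)
tree = simulate_tree(500, seed=4)
traits, _ = simulate_traits(tree, scenario)
results = [fit_paths(dag, traits, tree)
           for dag in candidate_dags("phenotype_response")]
print(rank_paths(results).round(3).to_string(index=False))
```

```
         model      C  df     p  q     cic  delta_cic   n
         mixed  1.505   2 0.471  8  17.798      0.000 500
      bergmann 44.472   6 0.000  6  56.642     38.844 500
         allen 54.748   4 0.000  6  66.919     49.120 500
null_allometry 97.715   8 0.000  4 105.796     87.998 500
```

The generating mixed model (temperature → mass and temperature →
appendages, plus allometry) attains the lowest CICc by a wide margin; its
standardized path coefficients recover the generating signs — a negative
temperature → log mass path (Bergmann, −0.342 ± 0.048) and a positive
temperature → log beak path (Allen, +0.173 ± 0.034).

The `examples/` directory holds one short script per capability
(signal + allometry, climate extraction, AIC ladders, path analysis, full
pipeline); each prints what it computes and what the numbers mean. A thin
CLI mirrors the pipeline: `ecorules simulate | climate | fit | pathfit`.

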