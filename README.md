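# shellforage

Two-island comparison and depletion modelling of tool-assisted shellfish
foraging by long-tailed macaques.

On two neighbouring Thai islands, macaque groups of very different size
(26 vs 4 tool users) crack rock oysters (*Saccostrea cucullata*) and marine
snails (*Planaxis sulcatus*, *Clypeomorus bifasciatus*, *Monodonta labio*)
with stone tools. Because the islands share environment and larval supply,
they form a natural experiment in predation pressure: if heavy tool-assisted
harvesting depletes prey, the crowded island should show smaller and scarcer
shellfish — and correspondingly smaller tools — than the sparsely populated
one. `shellforage` implements the full analysis chain for this design, for
behavioural ecologists and anyone studying size-selective harvesting with
clustered field data.

## What it computes

**Island-effect models.** Tool weight `w` is compared between islands on a
variance-stabilising scale with Koram (the crowded island) as reference:

* oyster tools — a random-intercept linear mixed model, fitted by maximum
  likelihood: `sqrt(w_ij) = β0 + β1·island_j + u_i + ε_ij`, `u_i ~ N(0, σ²_ID)`
  per tool user `i`; the island term is tested with a likelihood-ratio χ²
  (df = 1) against the intercept-only mixed model;
* snail tools (no user identities) — an ordinary linear model on `log w`
  with an F-form likelihood-ratio test;
* snail maturation — a linear model of the field size category on species,
  gonad maturation stage and island; under purely size-selective harvesting
  the island term should be null (same size at a given stage on both islands).

Each model carries a cluster-aware permutation companion (islands reassigned
over whole individuals, `p = (#{|T*| ≥ |T|} + 1)/(n_perm + 1)`, exhaustive
enumeration when feasible), leave-one-individual-out stability checks, and
report-only residual diagnostics.

**Resampling comparisons.** Prey sizes (oyster valve area `L×W`; snail
conical-shell volume `(1/3)π(W/2)²L`), per-plot transect counts, and natural
stone supply are compared by Welch t-tests plus 95% percentile-bootstrap
confidence intervals per island (1000 resamples), with the survey's
candidate-stone filter (drop stones lighter than 80% of the lightest
observed tool) applied first.

**Depletion model.** Consumption is extrapolated as
`annual = rate × users × 365` and set against the standing stock
`density × shoreline × 3 m strip`; the depletion ratio `annual/standing`
exceeding 1 means one year of foraging would consume the current stock
absent replenishment. A four-factor life-history screen (aggregation, size
at maturity, reproductive output, larval mode) classifies each prey species
as vulnerable, resilient or mixed.

A synthetic-data generator reproduces the whole survey design (93/93 oyster
tools from 14/4 individuals, 45/22 snail tools, 14 one-metre transects per
island, Poisson plot counts at the observed island means) so every stage is
testable and calibratable without the field data.

## Worked example

```python
import shellforage as sf
from shellforage.models import OysterToolModel, tools_to_frame

ds = sf.generate_dataset(sf.SimulationConfig(seed=1))
res = OysterToolModel(tools_to_frame(ds.analysis_tools(sf.Task.OYSTER))).fit()
print(res.summary())
```

```
OysterToolModel (ref = Koram)
----------------------------------------------------------
response  : sqrt(weight_g), n = 186
island    : E=1.999 SE=0.837 chi2(1)=4.925 p=0.02647 [sqrt(weight), n=186]
```

`E = 1.999` is the island effect on the square-root-gram scale: tools on the
sparse island are heavier (the generator planted a shift of 1.729, well
inside ±2 SE), and the likelihood-ratio test rejects equality of the island
means (χ²₁ = 4.93, p = 0.026) while accounting for repeated tools per
individual.

```python
profiles, rates = sf.generate_consumption_scenario()
koram = {p.island: p for p in profiles}[sf.Island.KORAM]
est = sf.island_depletion(koram, rates, ds.snail_transects)
print(f"area={est.foraging_area_m2:.0f} m2  density={est.density_per_m2}  "
      f"standing={est.standing_population}  annual={est.annual_consumption:.0f}  "
      f"ratio={est.depletion_ratio:.3f}")
```

```
area=4653 m2  density=14.5  standing=67469  annual=60736  ratio=0.900
```

Along 1551 m of accessible shoreline with a 3 m foraging strip (4653 m²),
this simulated periwinkle density of 14.5/m² gives a standing stock of
67,469 snails, while 26 tool users at 1.6 periwinkles per foraging hour
(4 h/day, 365 d) eat 60,736 a year — a depletion ratio of 0.90, i.e. nine
tenths of the stock annually, without replenishment.

The same analyses run from the shell on CSV survey tables:

```sh
shellforage simulate --seed 1 --out data/
shellforage compare-tools --tools data/tools.csv
shellforage depletion --profiles data/island_profiles.csv \
    --rates data/consumption_rates.csv --transects data/snail_transects.csv
shellforage run --config config.yaml --seed 1 --out results/
```

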