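# Methods

`shellforage` re-implements, as a tested pipeline, a two-island natural
experiment on tool-assisted shellfish foraging: a crowded island (Koram,
26 tool-using macaques) and a sparse one (NomSao, 4) with shared
environment and larval supply. This note records the models, the
conventions, and the design choices where the design was genuinely open.

## Data model and units

All masses are grams and linear dimensions millimetres; stone quadrats are
20 × 20 cm and snail transect plots 1 × 1 m, kept in their field units.
Islands are a strict two-level factor with Koram as the reference level
everywhere, so every island effect is "NomSao relative to Koram" on the
model's transformed scale. Tool analyses are restricted to adult males
(the sparse island hosts adult males only, and males use larger tools, so
mixed-sex data would confound the island contrast).

Two derived sizes are used. Oyster size is valve area `length × width`
(mm²): the opened valve is roughly elliptical and both dimensions are
measured. Snail size is the volume of a cone with the shell's width as
base diameter and length as height, `(1/3)·π·(width/2)²·length` (mm³) — a
deliberate first-order proxy for a spiral shell. Both are configurable
(`method=` `oyster_area` | `snail_volume` | `length_only`) because no
canonical formula exists for "size" here; conclusions should be checked
under `length_only` if the proxy is in doubt.

The candidate-stone filter retains quadrat stones weighing at least 80% of
the lightest tool observed in use ("20% smaller" is read on weight, the
only measurement recorded for every stone), inclusive at the boundary, and
drops stones whose longest measured dimension exceeds the plot side.

### A consumption-rate inconsistency, kept deliberately

The per-individual consumption figures are 36 oysters/day, 1.6
periwinkles per foraging *hour*, and 8.9 other items/day over 4 foraging
hours. The headline total of 46.5 items/day is the plain sum of the three
components — i.e. it counts the periwinkle figure as a daily number —
while the periwinkle-only extrapolation uses 1.6 × 4 h = 6.4/day. These
two readings are mutually inconsistent, but each is what the respective
reported total is built from, so `ConsumptionRates` keeps both: the
`daily_total` basis uses the component sum, the `hourly_periwinkle` basis
the hourly reading. The class warns about this in its docstring and the
default total can be overridden.

## Island-effect models

**Oyster tools.** `sqrt(weight)` with a fixed island effect and a random
intercept per tool user, fitted by maximum likelihood (not REML) so that
the island term can be tested by a likelihood-ratio χ² (df = 1) against the
intercept-only mixed model. The square root stabilises the right skew of
tool weights while keeping the scale interpretable. Fitting uses
statsmodels `MixedLM`; the Powell optimizer is tried first and gradient
optimizers serve as guarded backups, keeping the best finite-likelihood
solution — on these small two-group designs the default gradient method
can stall short of the optimum or collapse the random-intercept variance
to a spurious zero. If the individual variance is genuinely singular
(≤ 1e-8 of the residual variance) the fit falls back to the plain linear
model and flags this in the result.

**Snail tools.** No user identities exist (tools are collected at cracking
sites), so `log(weight)` is modelled by OLS with the island term tested by
an F-form likelihood-ratio test, df (1, n − 2). The OLS solution is the
closed-form normal-equations estimate.

**Maturation.** Response: the field size category (1–4) of each staged
snail; predictors: species, gonad maturation stage (ordinal, entered as
numeric), island, and island × stage. Two tests are reported: the full
model against the intercept-only null (does maturation structure shell
size at all?), and the island main effect with one numerator df, obtained
by dropping island from the additive model (species + stage + island vs
species + stage) — testing the interaction and main effect jointly would
use two df and blur the question "is a snail of a given stage the same
size on both islands?". Degrees of freedom are reported as computed from
the data actually supplied, not forced to any external convention.
*M. labio* never enters this model: it was too rare on the crowded island
to sample across size categories, so it cannot support a cross-island
contrast. An island covering fewer than two stages makes the interaction
design rank-deficient and is rejected with an explicit error.

**Diagnostics.** Residual checks are quantitative but report-only:
Shapiro–Wilk on residuals, a Breusch–Pagan-style variance regression on
fitted values, and the share of Cook's-distance-like leverage points above
4/n. Stability is assessed by refitting with each sampling unit excluded;
a unit is flagged influential when its exclusion moves the island estimate
by more than one full-fit SE (configurable; a 1e-8 absolute floor guards
degenerate zero-SE fits).

## Resampling machinery

**Permutation companion.** Island labels are reassigned at the level of
whole sampling units — all tools of one individual move together — keeping
the number of units per island fixed, and the model's own test statistic
is recomputed per relabeling. Two-sided p uses the add-one estimator
`(#{|T*| ≥ |T|} + 1)/(n_perm + 1)`, which can never return 0; when the
number of distinct relabelings is at most `n_perm` the test enumerates
them all and reports the exact p instead. Default `n_perm = 10000`;
individuals are the unit for oyster tools, records for snail tools.

**Bootstrap.** Percentile intervals of the mean (not BCa — the minimal
method matching the original procedure): `n_boot = 1000` resamples at the
original sample size, indices drawn as
`default_rng(seed).integers(0, n, size=(n_boot, n))`, interval from
`numpy.quantile` at (1−level)/2 and 1−(1−level)/2. Group comparisons
report both islands' intervals and whether they intersect, using
independent substreams spawned from one seed so the verdict is symmetric.

**t-tests.** Welch by default (unequal variances,
Welch–Satterthwaite df), with the pooled-variance form available; the df
is reported raw and rounded for display. Two groups that are both
constant raise a degenerate-variance error rather than fabricating a
statistic — all-zero transect counts surface this way.

**Size-comparison skip rule.** A taxon with fewer than 5 records on
either island yields a skip report instead of a test, generalising the
handling of the snail species with only 4 individuals found on the
crowded island.

## Depletion model

Foraging area = accessible shoreline × a 3 m strip width (the typical
width of the exploited littoral band). Transect density is total count /
total plot area, rounded **half-up to 2 decimals before scaling by area**;
standing stock is the rounded product. This rounding convention is what
makes the reported standing stocks reproducible exactly and is exposed as
a parameter. Annual consumption has two bases: `daily_total`
(items/day × users × 365) and `hourly_periwinkle`
(items/hour × 4 h × users × 365); an optional nearest-thousand rounding
matches report conventions. The depletion ratio is annual/standing
(ratio × standing = annual exactly, pre-rounding); years-to-depletion is
its reciprocal and is explicitly "without replenishment" — both main prey
species have planktonic larvae, so local recruitment does not track local
adults and no replenishment term is modelled. Degenerate stocks are
encoded as infinities, not errors. Half-up rounding is used wherever ties
can arise (e.g. 163.25 → 163.3), via decimal arithmetic rather than
binary-float rounding.

The vulnerability screen encodes four qualitative rules: high aggregation
→ slow recovery, large size at sexual maturity → slow recovery, high
reproductive output → fast recovery, attached (non-planktonic) larvae →
slow recovery. A species is `vulnerable` only if all four predict slow
recovery, `resilient` only if all four predict fast, otherwise `mixed`.
The built-in profiles classify both the rock oyster (high aggregation,
large at maturity, very high output, planktonic) and the tropical
periwinkle (high aggregation, small at maturity, low output, planktonic)
as mixed.

## Synthetic data generator

The generator draws datasets with exactly the dependency structure the
models assume, at the field design's sizes: 93/93 oyster tools from 14/4
adult males, 45/22 snail tools, 14 transect plots per island, 100 size
records per taxon and island, 7 stone-quadrat locations × 2 littoral
zones per island.

* Oyster-tool weights: `sqrt(w) = 8.0 + 1.729·island + u_i + ε`,
  `u_i ~ N(0, 1.0)`, `ε ~ N(0, 2.0)` (sqrt-gram scale; Koram mean ≈ 64 g,
  a plausible oyster-cracking stone, with the island shift matching the
  magnitude of the real contrast).
* Snail-tool weights: `log w = 3.3 + 0.585·island + ε`, `ε ~ N(0, 0.6)`
  (Koram median ≈ 27 g; snail tools are much lighter than oyster tools).
* Plot counts: Poisson with island × species means equal to the observed
  transect totals divided by 14 (e.g. periwinkles 12.9/plot vs 40.6/plot);
  a negative-binomial switch (`nb_dispersion`) adds overdispersion, off by
  default because no count model was reported.
* Prey dimensions: normal lengths/widths per taxon with a +4 mm island
  shift on length, truncated at zero by redraw. Redrawing slightly lifts
  the mean relative to the nominal parameter — accepted in preference to
  shifted or censored distributions, and negligible at the default
  mean/sd ratios.
* Maturation: four size categories per species × island; the latent stage
  is `1 + 0.25·(size − 0.75·base)` plus N(0, 0.5) noise, rounded and
  clipped to 1–4 — monotone in size and, by construction, identical on
  both islands, the null the maturation model should not reject.

One master seed drives everything through `SeedSequence` spawning in fixed
stage order (oyster tools, snail tools, transects, sizes, maturation,
stone quadrats), so each stage's stream is independent and reproducible.
Zero-effect configurations yield null datasets on which the two-group
stages reject at their nominal 5%.

What the generator does **not** emulate: spatial autocorrelation along the
shore, tide-dependent detectability, measurement error in calipers and
scales, non-normal tool-weight shapes beyond the transform, and any
predation feedback between years. Tests passing on synthetic data
therefore demonstrate that the machinery is correct and calibrated under
the assumed model, not that the field data satisfy those assumptions.

## Pipeline and reproducibility

`run_pipeline` executes whichever stages the provided tables support
(tool models, stone supply, availability, prey size, maturation,
depletion), writes one CSV per stage plus a JSON manifest recording the
master seed, every derived stage seed, replication settings and row
counts, and preserves completed outputs when a stage fails (non-OK bundle,
error recorded in the manifest). Reruns with the same configuration are
byte-identical. The acceptance script runs the headline computations at
these sizes: 60 mixed-model recovery replicates, 2000 permutations, 300
bootstrap-coverage replicates and 1000 type-I replicates — enough for the
Monte-Carlo error of each reported rate to be a few tenths of a percent.

## Known limitations

* **Small-cluster mixed-model intervals undercover.** With 14 + 4 tool
  users the island contrast has roughly 16 effective degrees of freedom,
  and ML variance components are biased low with few clusters; the Wald
  ±2 SE interval covers the true island effect in ≈ 91–92% of synthetic
  replicates rather than the nominal 95% (empirical SD of the estimate
  ≈ 0.65 vs mean reported SE ≈ 0.58 at the default design). This is a
  property of ML/Wald inference at this design, not a convergence issue —
  fits match an independent lme4 ML oracle to all printed digits. Treat
  the mixed model's SE as mildly optimistic; the permutation companion
  does not share this bias.
* The snail-tool model cannot account for repeated tool use by the same
  unknown individual; records are treated as independent.
* The depletion model is a static extrapolation: no recruitment, growth,
  seasonality or functional response, and the strip width is a single
  constant.
* The maturation model treats ordinal responses and predictors as
  numeric, matching the original linear-model design rather than an
  ordinal regression.
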