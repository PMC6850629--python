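# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `pollentraits`. It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Time conventions

Ages are calibrated years BP (larger = older). All collections are ordered in
ascending calendar time (descending BP), and internal computations use
t = −ageBP, so "previous" always means smaller t. Temporal distances for the
autocorrelation models are measured in units of 100 years; with the ~72-year
mean sample spacing this keeps the AR parameter φ numerically well scaled,
and the likelihood is invariant to the choice of unit.

## Proxy alignment

* δ¹⁸O and band width: piecewise-linear interpolation between bracketing
  measurements (exact at knots, no overshoot). Targets outside the measured
  range are held at the nearest endpoint with a logged warning — except band
  width, whose missing oldest section (the unlaminated part of the core) is
  imputed at a fixed 0.22 mm yr⁻¹, the band width at the onset of lamination.
  Interior band-width gaps are interpolated linearly in time.
* δ¹⁸O is multiplied by −1 to give a precipitation proxy (higher = wetter).
* Charcoal is never interpolated (interpolation would shrink the extremes
  that carry the fire signal). Two indices are computed: `fire_prev`, the
  closest previous measurement — "previous" reads *at or before*, so a
  measurement exactly at the pollen age is used — and `fire_max`, the maximum
  over the inter-sample window (previous pollen age, current pollen age] in
  calendar time. These windows partition time and use each charcoal point at
  most once; the oldest sample's window extends to the oldest measurement,
  and an empty window falls back to `fire_prev` (logged). Every regression is
  run with both indices and the lower-AIC model kept (ties go to `fire_prev`;
  if AIC and pseudo-R² disagree, AIC decides and the disagreement is logged).
* The Pearson correlations between the two fire indices and between erosion
  and each fire index are reported as diagnostics only; they never gate the
  pipeline.

## Trait aggregation

Species records aggregate to genus or family means under the inclusion rule:
a taxon-trait cell is used only if ≥ 3 species have data, or the taxon is
known to have fewer than nine species and ≥ 30 % of them have data. When the
true species count is unknown only the first clause can pass; by default the
species table is treated as a census of each taxon. Leaf area is averaged on
the raw scale and the taxon mean then ln-transformed (`log_before_mean=True`
gives the other ordering; the choice is recorded in the audit table). Boolean
traits take a strict species majority; exact ties leave the cell absent.
Family means use *all* species records of the family, including species of
genera that are themselves included — this is flagged in the audit table.
Usefulness is a property of the taxon metadata (the 'useful' genus list), not
of species records.

Two taxonomic resolutions are supported, genus-only and genus + family; the
pipeline can run both and writes a side-by-side coefficient comparison.
Because family-level pollen taxa contribute genuinely new abundance
information, coefficients are expected to agree approximately (mean absolute
difference ≪ 0.1 when traits are fully conserved within genera), not exactly.

## Community properties

Eight per-sample properties: CWM wood density, CWM ln leaf area, CWM adult
height, CWM seed mass, % compound-leaved, % zoochorous, % useful, and the
Poaceae : tree pollen ratio. CWMs and percentages use counts directly —
identical to proportions by scale invariance (asserted by test). Taxa without
data for a trait drop out of both numerator and denominator; the fraction of
tree pollen they represent is reported as per-trait coverage. The % useful
denominator additionally includes Arecaceae; the Poaceae : tree ratio uses all
tree pollen regardless of rank. Coverage denominators use tree pollen (not
all pollen); missing property cells propagate to the regressions, which
delete listwise per response and report n.

## Redundancy analysis and restricted permutations

RDA centres the response columns (standardizing them when units differ, as
for the CWM trait matrix), regresses on the centred constraints, and
eigendecomposes the fitted and residual covariances; constrained plus
unconstrained variance equals the total (checked to 1e−8, and cross-checked
against R vegan in the tests). Constraint significance uses marginal tests
(each given the others) with pseudo-F statistics referenced to cyclic shifts
of the year ordering — the restricted scheme appropriate to a single
autocorrelated series; with n samples there are n − 1 distinct non-identity
shifts (93 for 94 samples), all of which are used, making the test
deterministic. p = (1 + #{F* ≥ F}) / (1 + n_perm) is never zero.

## Fourth-corner model

The stacked log-linear model

log E[n_it] = α_t + γ_i + Σ_kj β_kj E_kt z_ij

is fitted by iteratively reweighted least squares via a standard GLM routine.
Year effects α_t absorb the fixed 300-grain counting total (the compositional
constraint); taxon effects γ_i absorb baseline abundance. Environments and
traits are z-scored before fitting so β values are per-SD and comparable
across pairs (an unstandardized mode exists, in which doubling a trait halves
its β). The default family is negative binomial — pollen counts are
overdispersed — with the dispersion α estimated by method of moments from the
Poisson fit of the no-interaction model and held fixed in both models so their
deviances are comparable. Constant trait columns are dropped from the
interactions (logged, β reported as missing). When IRLS lands in a small
two-point limit cycle (a known behaviour on strongly overdispersed tables),
the fit is polished by L-BFGS from the IRLS iterate and accepted only if the
optimizer converges.

Significance is an analysis of deviance, LR = deviance(no-interaction) −
deviance(full), referenced to a *parametric* bootstrap: counts are resampled
from the fitted no-interaction model (gamma–Poisson for the negative
binomial), both models refitted, with p = (1 + #{LR* ≥ LR}) / (1 + 99). The
parametric scheme is a well-defined, reproducible contract; its type-I error
is verified by simulation in the acceptance tests.

## GLS with continuous-time AR(1) errors

Each community property is regressed on precipitation, erosion rate and one
fire index under y = Xβ + ε with corr(ε_s, ε_t) = φ^(|Δt|/100 yr), suited to
irregular spacing. Response and predictors are z-scored over the usable rows,
so β are standardized effect sizes (adding a constant to a predictor leaves
its β unchanged). Estimation is maximum likelihood — not REML — so AIC
comparisons between the two fire-index variants are coherent; the parameter
count for AIC is p coefficients + σ + φ (φ omitted when fixed). The profile
log-likelihood over φ is evaluated on a 50-point grid on [0, 0.98] and
refined by golden-section search; β then follows in closed form through the
Cholesky factor of the correlation matrix. φ = 0 reproduces OLS exactly; a
boundary estimate raises a warning. Standard errors use σ̂² = RSS_w/(n − p)
with Wald t p-values at n − p df. The pseudo-R² is 1 − RSS/TSS on the
unwhitened standardized response at the GLS coefficients (so it can be
negative, and never exceeds 1). Fits need ≥ 8 usable rows when φ is
estimated.

## Trait-shuffle permutation envelope

The headline significance criterion for the seven trait-based properties (the
Poaceae : tree ratio is not a trait and is excluded) is a permutation null:
whole trait-table rows are shuffled across taxa — each taxon keeps a coherent
trait set, preserving trait covariance — the CWM series recomputed, and the
GLS refitted per property with the fire index fixed at the observed fit's
choice. The central 95 % interval of each coefficient over 1000 shuffles is
the envelope; an observed coefficient counts as significant-beyond-null only
outside it. Wald p-values are reported alongside, but the envelope is the
conservative criterion.

Implementation: the correlation Cholesky factors and whitened design depend
only on (φ, rows, X), so they are precomputed per φ-grid point and shared
across all shuffles and properties; φ is resolved on the grid for the
shuffled fits (the golden-section refinement changes β negligibly). A shuffle
yielding an all-missing property column is resampled (logged); a property
that is constant over time (e.g. a trait constant across taxa) has β = 0 by
convention and a zero-width envelope. For ≤ 8 taxa the permutations can be
enumerated exhaustively instead of sampled.

This null is deliberately conservative: a shuffled trait landing on an
abundant, environmentally responsive taxon produces large spurious
coefficients, so the envelope scales with the very signal being tested. In
practice the observed-to-null separation is capped near z ≈ 2–2.5 at
70 genera (it grows with the number of taxa carrying trait data and with
cross-trait syndrome correlation, and shrinks when a few hyper-responsive
taxa dominate). Strong genuine effects can therefore sit *inside* the
envelope while being highly significant by Wald tests — users should read
the two criteria together.

## The synthetic-data generator

The generator emulates the structure of a ~7000-year tropical lake record:
94 samples over 6860 years at irregular spacing (gaps uniform in
[12, 179] yr, deviations rescaled to hit the span exactly; mean ≈ 73.8 yr),
300 grains per sample (multinomial — closed counting, inducing the
compositional constraint), 70 tree genera plus 25 family-level tree taxa
(baseline log-abundances chosen so the genus/family pollen split is roughly
58/42), Poaceae (fire-responsive, openness signal) and Arecaceae (counted in
the % useful denominator), 383 δ¹⁸O and 470 charcoal measurements at
irregular ages, and a band-width series absent for the oldest 28 % of the
span.

Each environmental driver is a standardized continuous-time AR(1) latent
process (default correlation 0.7 per 100 yr) sampled exactly at the union of
pollen and proxy ages. The proxies are noisy transforms: δ¹⁸O = −latent +
N(0, 0.15²); band width = 0.22·exp(0.4·latent) mm yr⁻¹; charcoal =
exp(1 + 0.4·latent + N(0, 0.1²)) scaled up multiplicatively by Poisson-timed
spike events (fires cluster in high-fire periods; ~1 event per 2000 yr,
amplitude ~e^N(1.0, 0.4), 15-yr decay). The latent environment is never
emitted — only the proxies — so alignment is exercised end to end.

Genus-level traits are drawn from two correlated syndromes, as in real
floras: a stature/dispersal axis (tall, large-seeded, zoochorous genera
covary) and a conservative axis (dense wood with compound leaves), each with
loading 0.7 (pairwise genus-trait correlation ≈ 0.5); leaf area is
independent of both. Species values scatter around genus means with a
configurable within-genus correlation (default 0.7 — the share of
species-level variance explained by genus, comparable to empirical
wood-density conservatism); flags flip in species with probability
0.2·(1 − correlation). Wood density is truncated-normal(0.6, 0.15) on
(0.1, 1.2) g cm⁻³; leaf area, height and seed mass are log-normal. Individual
cells go missing with per-trait probabilities (2–25 %) so the inclusion rule
and coverage diagnostics are exercised.

Abundances respond to the latent environment through planted per-SD
interaction coefficients c(environment, trait); taxa with missing traits
respond neutrally. All randomness flows from one seed through
`SeedSequence.spawn` (stages: ages, environment, traits, counts; the pipeline
spawns further children for the RDA, bootstrap and shuffle stages), giving
byte-identical reruns.

`power_study_config` is the planted-effects configuration used for
end-to-end recovery runs: the human-disturbance direction set (fire → taller,
larger-seeded, zoochorous; erosion → denser wood, compound leaves) at
magnitude 0.9 per SD, environmental persistence 0.3 per 100 yr, syndrome
loading 0.8 and near-complete trait coverage. The magnitude sits where signal
is not yet offset by the response-amplitude inflation of the shuffle null
described above; under these conditions the planted signs are recovered
essentially always, the two erosion pairs escape the envelope in ~90 % of
runs, and the fire pairs — attenuated by the charcoal proxy chain — in
~40–70 %.

### What the generator does and does not emulate

It reproduces the record's dimensions, irregular spacing, closed counting,
genus/family mixture, proxy irregularity and the missing band-width section.
It does **not** emulate pollen-productivity and dispersal biases, taxon
dominance as extreme as real tropical records (moderate dominance keeps CWMs
from being hostage to two or three taxa), mechanistic vegetation dynamics, or
chronological (age-model) uncertainty. Passing tests therefore demonstrate
that the estimators are correct and calibrated under a realistic data
*structure*; they do not show that real pollen-derived CWM trends equal
vegetation trends — for that, the standard relative-trends argument applies.

## Numerical choices and degenerate inputs

* Interpolation is exact at knots; ties in "closest previous" resolve to the
  measurement at the pollen age.
* Rank-deficient RDA constraints raise an error naming the collinear columns
  (QR with pivoting).
* Permutation and bootstrap p-values are computed with the +1 convention and
  can never be zero; all are deterministic under a fixed seed.
* GLS responses with zero variance raise an error (or, inside the envelope,
  yield β = 0 by convention); φ at the grid boundary warns.
* Fourth-corner fits reject non-integer or negative counts, and incomplete
  trait rows, up front.

## Known limitations

* The trait-shuffle envelope's conservatism (above) is intrinsic to the
  method, not to this implementation; detection of genuine community-level
  effects through it requires many trait-bearing taxa and a faithful proxy.
* The fourth-corner bootstrap is parametric (resampling from the fitted
  no-interaction model); residual-based or case-resampling schemes are not
  implemented.
* The negative-binomial dispersion is a single moment-matched constant shared
  by the compared models rather than jointly profiled.
* No phylogenetic imputation of missing traits, no pollen-productivity
  correction, no age–depth modelling: ages are inputs.
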