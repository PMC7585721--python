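# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices made where the design was genuinely open, and what
the tests do and do not establish.

## Observation model and measurement error

Each trait is modelled independently. For individual *i* at site *j(i)*,

    z_i   = x_i' β + u_{j(i)},   u_j ~ Normal(0, σ_site²)
    y_i   = z_i + c_i + e_i,     e_i ~ Normal(0, σ² + τ_i²)

where `x_i` codes isolation, origin, sex, year and the four interaction
terms as 0/1 indicators (reference levels continuous / field / male /
2008; interaction columns are products of their parents), and `(c_i, τ_i)`
is the instrument layer: `(0, 0)` for digitally measured rows, and the
calibration posterior mean and sd of the calliper−digital offset for
calliper rows. This is the *marginalised* form of a latent-variable
model in which calliper rows observe the true size plus an uncertain
additive conversion: rather than sampling `z_i` explicitly, the
conversion uncertainty is folded into the observation variance. An
alternative reading would give `z` its own individual-level variance
distinct from the residual observation error; with a single measurement
per individual the two variances are not separately identifiable, so the
single-residual form with instrument-specific extra variance is used.
This interpretive choice is deliberate and affects nothing observable at
one measurement per individual per trait.

The calibration itself is an additive offset per trait, estimated from
paired calliper/digital measurements of the same individuals: with
differences `d_k`, sample mean `d̄` and sample sd `s`, the posterior under
a Normal(0, 10²) mm prior is the conjugate normal-normal form

    offset | d ~ Normal( (n/s²) d̄ / (1/10² + n/s²),  1/(1/10² + n/s²) ).

The noise sd is plugged in as the sample sd rather than given its own
prior; at the calibration sample size (48 pairs, 24 per sex-limited
trait) the difference to a full unknown-variance treatment is negligible
for the offset mean and keeps the estimate in closed form. A
slope-and-intercept regression alternative was considered and rejected:
the two instruments measure the same physical length, so a unit slope is
the structurally correct assumption, and the paired correlations
(r ≥ 0.85 by construction of the generator, ≥ 0.97 in practice) leave a
slope nearly unidentified over the narrow within-trait range.

Sexes are pooled in the calibration (no sex-specific offset); the
instrument error is attributed to the instrument, not the observer.

## Priors

* intercept: Normal(5, 100²) mm — centred on a positive baseline at
  trait scale, effectively flat;
* betas: Normal(0, 100²) mm — direction-neutral;
* σ_site, σ: half-normal with scale 10 mm — positive support, weakly
  informative far above any plausible value.

The exact prior sds are package choices (only "wide" is prescribed by the
problem); `TraitModelResults.prior_flatness()` verifies after every fit
that each prior is flat over the range the posterior occupies (density
ratio across the posterior 95% interval > 0.99 in the test suite), which
is the operative definition of "minimally informative" here.

## Sampler

The default protocol is two independent chains, 10,000 burn-in
iterations, 10,000 retained draws, thin 1, fully seeded (identical
settings reproduce identical draws). The kernel is blocked Gibbs:

* β — conjugate weighted-least-squares normal draw (observation weights
  `1/(σ² + τ_i²)`);
* u_j — independent conjugate normal draws;
* σ_site — slice sampling on log σ_site against the *collapsed*
  likelihood (site effects integrated out analytically: the weighted site
  mean is marginally Normal(0, σ_site² + 1/Σw)), which removes the
  funnel coupling between u and σ_site that cripples mixing with only
  four sites;
* σ — slice sampling on log σ;
* two exact "sweep" draws along the likelihood-flat directions that
  trade the site effects off against the intercept (continuous sites)
  and the isolation coefficient (isolated sites). With two sites per
  isolation class these directions are identified only by the priors, and
  resampling them from their exact Gaussian conditionals replaces a slow
  random walk with an independent draw.

All moves leave the exact posterior invariant; no approximation is
introduced. Convergence is monitored with rank-normalised split-R̂ and
bulk ESS (via arviz) with a 1.05 flag threshold — an automated surrogate
for visual trace inspection. Non-convergence raises a warning, never
passes silently.

Model checking uses posterior-predictive Bayes-P values for the mean and
the coefficient of variation of the (conversion-adjusted) observations,
with the conventional 0.1–0.9 pass band.

## Group predictions and contrasts

Predictions evaluate the linear predictor at a group's indicator settings
per posterior draw. Two policies, both implemented:

* **site handling** — population-level predictions average the posterior
  site-effect draws over the sites of the relevant isolation class;
  site-specific predictions use that site's own effect.
* **year handling** — `"mix"` (default) averages the prediction over the
  group's empirical 2008/2010 composition, matching a single "field
  grown" column that spans both cohorts; a reference year can be
  requested instead. Laboratory cohorts are entirely 2010 either way.
  On the default synthetic data the two policies differ by at most the
  year effect (≤ 0.1 mm); both are exposed so the difference can be
  inspected on any dataset.

The "general" rearing condition averages the field-only and
laboratory-only contrast draws with equal weight, draw-wise; its mean
therefore always lies between the condition-specific means and its sd is
smaller than either, matching the behaviour of a pooled summary.
`P_iso>con` is the exact fraction of difference draws strictly above
zero; displayed probabilities are rounded to three decimals.

An important consequence of the site-handling policy: the contrast
*conditions on the realised sites*. With two sites per class, the
posterior of the class difference concentrates near the realised
difference of site means. This is the appropriate inference for "are
these isolated populations bigger than these continuous ones", but it
means that under a generating process with between-site scatter and no
isolation effect, confident directional probabilities are *correct*
detections of realised site differences, not false positives. The null
calibration of the machinery is therefore tested with both the betas and
the between-site variance at zero (true class difference exactly zero),
while interval coverage of the betas — whose posterior does carry
site-level uncertainty — is tested with site scatter present.

## Synthetic-data generator

The generator is the package's stand-in for the deposited specimens and
defines the conditions every end-to-end test runs under:

* **design** — the exact per-cell counts of the four-site study
  (two continuous sites KAA, TAL; two isolated sites ALA, VAS; field
  2008, field 2010 and laboratory-2010 cohorts; 333 adults in total),
  with the field-2008 cohort assigned to the calliper instrument;
* **effects** — per-trait intercept and betas solved exactly from the
  published group-estimate table, so the configured cell means equal the
  published posterior means (reference cell = continuous/field/male);
  the between-year effect is not published and defaults to a small
  positive shift (0.02–0.10 mm by trait) that cancels in every
  isolated-minus-continuous contrast;
* **noise scales** — residual sds (0.2–0.9 mm by trait) back-calculated
  from the published posterior sds of group means at the published group
  sizes, and site sds (0.04–0.15 mm) from the spread of site-specific
  estimates within an isolation class. These are artifact choices: the
  originals are not recoverable from published summaries;
* **instrument layer** — calliper rows carry a +0.30 mm offset with
  0.05 mm noise; dual-measurement pairs add a small digitisation noise
  (0.02 mm) to the recorded value, yielding paired correlations ≥ 0.97;
* site effects are drawn once per (site, trait) and shared by all
  individuals of the site — the random-intercept structure the model
  assumes; sex-limited traits are generated only for the matching sex.

What the generator does **not** emulate: non-normal residuals, observer
effects, missing-data patterns of real field collections,
trait–trait correlations within individuals, and any genetic or
evolutionary process (it reproduces statistical structure, not gene
flow). Passing tests therefore demonstrate that the pipeline recovers the
truth *under the model's own assumptions* at the study's sample sizes —
they do not validate those assumptions against real specimens.

## Problem sizes and test design

Tests and the acceptance script scale the sampler down from the
10k/10k default: 800–1,500 burn-in and retained draws per chain are ample
for this ~15-parameter model given the collapsed/sweep updates
(bulk ESS > 500 for every parameter at 1,500 draws), and keep the full
suite near a minute. The acceptance script averages its quantities over
12 replicate simulated studies so that between-site realisation noise
(sd ≈ site_sd per replicate for a class contrast) shrinks by √12 and the
reported values reflect the configured structure rather than one draw of
four site effects.

Recovery checks compare fitted quantities to the *realised* generating
truth (configured linear predictor plus that replicate's site draws) in
posterior-sd units, aggregated as a chi-square-like bound over the
full set of group cells, since a per-cell 2-sd criterion would fail ~5%
of cells by construction.

## Known limitations

* Two sites per isolation class: the isolation effect is confounded with
  site identity; everything said about "isolation" is strictly about
  these four populations. The model quantifies, but cannot remove, this.
* The calibration plug-in sd slightly understates offset uncertainty at
  very small pair counts (n < 10).
* σ_site is weakly identified from four sites; its posterior is diffuse
  by necessity and sensitive to the half-normal scale in its upper tail.
* The single-residual measurement model is an interpretive choice (see
  above), indistinguishable from a two-variance model at one measurement
  per individual.
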