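# cricketsize

Bayesian hierarchical analysis of body-size divergence between genetically
isolated and continuous populations of Roesel's bush-cricket
(*Metrioptera roeselii*), with instrument-calibration measurement-error
propagation.

## The problem

Isolated populations of *M. roeselii* at the northern range margin are
larger than latitudinally matched populations inside the species'
continuous range. Is that divergence genetic, or just phenotypic
plasticity? The study design answers this with a common-garden comparison:
adults wild-caught at four sites (two continuous-range, two isolated) in
2008 and 2010, plus adults reared from field-collected nymphs under
identical laboratory conditions. If laboratory-reared crickets show the
same isolated-vs-continuous size difference as wild-caught ones, the
difference is genetic.

A measurement wrinkle makes the statistics interesting: the 2008 cohort
was measured with hand-held callipers, everything later with digital
landmark photography. A calibration subset (48 individuals measured both
ways) lets the calliper readings be converted to the digital scale — but
the conversion is uncertain, and that uncertainty must propagate into the
final estimates.

## The model

Per morphological trait (hind femur, forewing, pronotum, and the
sex-limited genital appendages — male cerci, female ovipositor), the
latent true size of individual *i* at site *j(i)* is

```
z_i = x_i' β + u_j(i),        u_j ~ Normal(0, σ_site²)
```

with fixed effects for isolation, rearing origin, sex, year and the
isolation×sex, isolation×origin, origin×sex, isolation×origin×sex
interactions (reference levels continuous / field / male / 2008), and a
site random intercept. Digitally measured rows observe `z_i` with residual
variance σ²; calliper rows observe `z_i + conversion`, where the
conversion offset posterior (mean ± sd from the calibration pairs) enters
as an observation-level shift plus extra error variance. Genital traits
drop the sex terms and are fitted per sex.

Priors are minimally informative (intercept centred on 5 mm with a wide
sd, betas on 0; half-normal priors on the sds). Sampling is a Gibbs
sampler with slice-sampled variance components, two chains with 10,000
burn-in and 10,000 retained draws by default, checked with split-R̂,
effective sample size, and posterior-predictive ("Bayes-P") checks on the
mean and coefficient of variation (pass band 0.1–0.9).

The headline quantity is the posterior of a group difference — isolated
minus continuous, per sex and rearing condition — obtained by draw-wise
subtraction of group predictions, and the directional probability
`P_iso>con`, the fraction of difference draws above zero.

Because the original specimens are not shipped with the package, a
first-class synthetic-data generator reproduces the study's statistical
structure: the exact per-cell sample sizes of the four-site design, group
means configured to the published estimates, site intercept scatter,
residual noise, and the dual-instrument offset. Every stage of the
pipeline is tested against it.

## Worked example

```python
import cricketsize as cs
from cricketsize import contrasts as ctr

design  = cs.default_study_design()        # 4 sites, 333 adults
effects = cs.default_study_effects()       # group means as published
records = cs.simulate_individuals(design, effects, seed=1)
pairs   = cs.simulate_dual_measurements(records, effects, n_pairs=48, seed=2)

conv = cs.fit_conversion(pairs, "femur")
# ConversionEstimate(trait='femur', offset_mean=0.292, offset_sd=0.009,
#                    n_pairs=48, pearson_r=0.999)

res = cs.TraitModel(records, "femur", conversion=conv).fit(
    chains=2, burn_in=2000, samples=2000, seed=3)
res.summary().round(2)
#               mean    sd  ci_2.5%  ci_97.5%  rhat  ess_bulk
# intercept    13.05  0.37    12.57     13.57   1.0   3708.56
# isolation     0.41  0.50    -0.28      1.13   1.0   3716.24
# origin       -0.49  0.16    -0.81     -0.17   1.0   3978.51
# sex           0.86  0.20     0.46      1.25   1.0   3736.12
# ...
# site_sd       0.23  0.47     0.00      1.33   1.0    540.31
# residual_sd   0.71  0.03     0.65      0.77   1.0   3254.41

lab = ctr.isolation_contrast(res, "laboratory", sex="male")
# ContrastResult(femur: 0.57 +/- 0.15 mm, P(>0)=1.000)
```

Reading the output: the calibration recovers the configured 0.30 mm
calliper offset with high paired correlation; the fitted model estimates
laboratory-reared males from isolated populations to be 0.57 ± 0.15 mm
longer in the femur than continuous-population males (generating value
0.51 mm plus this realisation's site scatter), with essentially certain
direction — the pattern that, surviving laboratory rearing, indicates a
genetic rather than plastic difference.

The same pipeline runs from the shell:

```
cricketsize simulate --seed 1 --out run/
cricketsize report --data run/morphometry.csv --pairs run/calibration_pairs.csv \
    --out run/results --seed 2
```

which writes the group-estimate, isolation-difference and site-specific
tables as CSV, a diagnostics JSON, and a forest plot of the differences
standardised to the continuous group.

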