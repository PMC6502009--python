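# Methods

## Estimand and estimator

The analysis unit is the procedure (one row per primary hip replacement;
bilateral patients contribute independent rows).  Failure is the first
linked surgical revision.  Follow-up runs from the primary operation to the
earliest of revision, death and the administrative extract date, measured in
365.25-day years from integer day counts; a revision recorded on the same
day as death counts as a revision.  Records whose derived follow-up is not
positive are rejected as zero-follow-up.

Net failure — the probability of revision in a hypothetical world without
death — is estimated as one minus the Kaplan-Meier survival function for
revision, with death treated as non-informative censoring.  The variance is
Greenwood's: `Var[F̂(t)] = Ŝ(t)² Σ dᵢ/(nᵢ(nᵢ−dᵢ))` over event times `τᵢ ≤ t`.
Net failure is the registry convention; it is *not* the real-world
cumulative incidence in the presence of death (which a competing-risks
estimator would target and which is deliberately out of scope).

Numerical conventions, chosen for determinism and tested at the boundaries:

* Tied times form one risk-set step; censorings recorded at an event time
  leave the risk set after the events at that time.
* The risk set at `t` counts subjects with no event or censoring strictly
  before `t`, excluding subjects whose event falls exactly at `t`.  This is
  the only convention under which `n_at_risk + n_events_by_t ≤ n_entered`
  holds when a horizon coincides with an event time.
* Day counts are exact integers in float64, so dividing by the single
  constant 365.25 cannot split ties; no rational-number time type is needed.
* If the last risk-set step has `d = n` (everyone fails), F̂ is 1 and the
  Greenwood SE is flagged undefined rather than given a fabricated value.
* Evaluating beyond the last observed time returns the last value flagged
  `extrapolated`, never a silent extension.
* F̂ is non-decreasing in `t`, as is the Greenwood *sum* `Var/Ŝ²`.  The
  variance itself is not monotone in general — the `Ŝ²` factor shrinks once
  F̂ exceeds one half — though at registry-scale failures (≪ 50%) it is in
  practice.

Single-construct reporting intervals use the complementary log-log
transform on survival, mapped to the failure scale.  The transform is a
design choice: it keeps intervals in [0, 1] and is asymmetric in the
direction observed for small failure probabilities; other registry software
may use the log or identity transform and will differ slightly.  When
F̂ = 0 the interval is `[0, 1 − (α/2)^{1/n}]` (the exact no-event upper
bound on the risk set at `t`); when F̂ = 1 the mirrored lower bound is used.

A nonparametric bootstrap SE (resampling subjects with replacement) is kept
in the package as a verification oracle for the Greenwood formula; it is
never used in the analysis path.

## Reference selection and the non-inferiority test

Within each stratum and horizon the reference is the construct with the
lowest F̂(t) among those with at least 1000 procedures still at risk at `t`
(at that size the construct's own CI is a few tenths of a percentage point
wide, narrow enough to anchor comparisons).  Ties break toward the larger
risk set, then the lexicographically smaller normalised construct key; the
rule matters only for determinism.  A stratum/horizon without any eligible
construct is reported as skipped — a first-class output, since the paucity
of long-horizon data is itself a finding.

Margins are stated as relative risk increases (20% and 100%) but the test
operates on the difference scale, so each margin is absolutised against the
estimated reference failure: `δ_m = m · F̂_ref(t)`.  This is the only
operationalisation consistent with classifying the *difference's* CI
against a margin.  The pooled SE is `√(GSEₓ² + GSE_ref²)`; the difference
carries an untransformed two-sided 95% Wald interval, and
`z_m = (diff − δ_m)/SE` is oriented so that small values support
non-inferiority (`ci_low > δ ⟺ z > z_{0.975}` — the CI and test are dual).
The CI drives classification; inclusive/strict inequalities follow the
classification rules exactly (non-inferior uses ≤, inferior uses >) and the
boundary cases are unit-tested.  When the reference has zero estimated
failure, δ = 0 and non-inferiority would require the difference's upper
limit to be ≤ 0; the rules are applied as written rather than
special-cased, and such cells are practically always inconclusive.  When
the pooled SE is zero (no events in either arm) the interval degenerates to
a point and is flagged.

The reference appears in its own output row with an exactly zero difference.
Classification counts are computed over display-eligible constructs
(≥ 500 at risk); constructs with 250–499 at risk are exported in the tables
but excluded from headline counts.  Both counting conventions are emitted:
"inferior by at least 20%" (including the 100% subset) and the 100% subset
itself.  No multiplicity adjustment is applied across the many construct
comparisons — a documented limitation of the design, not an omission.  A CI
wholly below zero is still labelled non-inferior; superiority is not a
label in this scheme.

The historic sensitivity mode pins the reference at the earlier horizons to
the construct selected at the longest horizon, re-estimating that
construct's failure at each earlier horizon from the same records.  Results
at the longest horizon are identical across modes by construction.  When
the historic reference performs worse than the contemporary one, every
difference falls and every margin grows, so no construct's label can move
toward inferiority — a monotonicity property the tests assert.

## Synthetic registry generator

The generator exists so every downstream stage can be exercised against a
known estimand; real extracts are confidential.  Defaults describe a
plausible national registry; each is a free choice documented here, not an
estimate from data.

* **Usage counts**: truncated discrete power law `P(k) ∝ k^−a` on
  [2, 25000], `a = 2.0`, for 1000 constructs — heavy skew, so only a small
  fraction of constructs ever reach the at-risk thresholds, reproducing the
  eligibility funnel qualitatively.  The pipeline-scale demo configuration
  (500 constructs, `a = 1.5`, max 30000) realises ≈ 100k procedures with
  several reference-eligible constructs per stratum.
* **Revision times**: per-construct Weibull.  Shape ~ Uniform(0.8, 1.4)
  spans early-failure (< 1) and wear-driven late-failure (> 1) profiles;
  instead of a scale distribution, each construct draws its baseline
  10-year net failure log-uniformly from [1%, 10%] and the scale is solved
  from it, pinning the clinically meaningful magnitude.
* **Stratum effects**: multiplicative cumulative-hazard factors, men 1.15
  vs women 1.0, ages < 55 / 55–75 / > 75 at 1.6 / 1.0 / 0.75 — younger
  patients revise more, with a mild gender contrast.  So in cell (g, b),
  `F*(t) = 1 − exp(−c_g c_b (t/λ)^k)`, the closed-form ground truth.
* **Death**: exponential, rates 0.004 / 0.015 / 0.06 per year by age band,
  men × 1.25; independent of revision time within each cell.
* **Demographics**: 60% women; age bands with probabilities 0.12 / 0.63 /
  0.25 and uniform integer ages within bands.  Enrollment uniform over
  April 2003 – December 2016 (each primary at least one day before the
  extract date), administrative censoring 31 December 2016.
* **Reproducibility**: one seed sequence per registry; construct parameters
  and each construct's records use deterministically spawned child streams,
  so identical configs are byte-identical.

Times convert to dates at day resolution (minimum one day), a ≤ 0.5-day
perturbation that is negligible against the horizons of interest.

For marginal strata the ground-truth net failure is the demographic-mix
average of the cell values.  Death rates and revision hazards share the
age/gender covariates, so in *pooled* strata censoring by death is mildly
informative and 1-KM recovers the mixture estimand only approximately; the
recovery tests therefore run within single cells, where independence is
exact.  The same caveat applies to pooled analyses of real registries.

What the generator does not emulate: dependent censoring, patient frailty,
surgeon/unit clustering, calendar-time improvement of implants or practice,
liner-material heterogeneity within a construct, and linked bilateral
procedures.  Passing tests show the statistical machinery is correct under
the stated model, not that real-registry biases (selection, confounding by
indication) are absent.

## Problem sizes in tests and the acceptance script

Simulation checks use sizes chosen to give tight Monte-Carlo error while
keeping a default run quick on one core: 50 seeds × 2000 bootstrap
resamples for SE agreement, 5000 replicates for the type-I error of the
classification (n = 1000 per arm, true failure 2%), 2000 replicates per
sample size for power monotonicity, 200 seeds for the three-construct
(2%/2%/6%) fixture, 100 seeds × 4000 procedures for estimand recovery, and
a ≈ 112k-procedure registry for the end-to-end determinism and structure
checks.  The acceptance script re-runs the same computations from scratch
with all randomness derived from its `--seed`.

## Known limitations

* Net failure, not cumulative incidence; no competing-risks estimator.
* No covariate adjustment beyond stratification; no causal interpretation.
* The choice of CI transform for single-construct reporting affects the
  printed intervals (not the classification, which uses the Wald interval
  of the difference).
* Margins are absolutised against an *estimated* reference failure; the
  extra variability of F̂_ref enters only through the pooled SE, not the
  margin itself — the test is conservative for true differences of zero
  (measured type-I error ≈ 1% at a nominal one-sided 2.5%).
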