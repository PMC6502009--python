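# implantbench

Non-inferiority benchmarking of hip prosthesis constructs from
procedure-level arthroplasty registry data.

National joint registries record hundreds of thousands of primary hip
replacements performed with thousands of distinct *constructs* — a femoral
stem brand, an acetabular cup brand and a bearing couple implanted together.
Externally set benchmarks (e.g. ODEP grades) dichotomise construct
performance against a fixed revision-rate bar; they say nothing about how a
construct compares with the *best available* alternative for a patient of
the same age and gender.  `implantbench` implements the internal-reference
alternative: within each stratum the best-performing, sufficiently used
construct becomes the benchmark, and every other construct is tested against
it with a non-inferiority design.  It is intended for registry analysts and
methods researchers; because real registry extracts are confidential, the
package ships a synthetic registry generator with closed-form ground truth
so the entire pipeline is testable and demonstrable end to end.

## Method

For each construct *x*, net failure at a horizon *t* (3, 5, 7 and 10 years)
is estimated with the product-limit (Kaplan-Meier) method on revision as the
event, censoring at death or the administrative extract date:

```
F̂(t) = 1 − ∏_{τᵢ ≤ t} (1 − dᵢ/nᵢ),     Var[F̂(t)] = Ŝ(t)² Σ_{τᵢ ≤ t} dᵢ / (nᵢ(nᵢ − dᵢ))
```

This is *net* failure — the probability of revision in a hypothetical world
without death — which is the standard registry estimand.  Within a stratum
(overall, by gender, or by gender × age band `<55 / 55–75 / >75`), the
reference is the construct with the lowest F̂(t) among those with ≥ 1000
procedures still at risk at *t*.  Each construct with ≥ 500 at risk
(≥ 250 for tabular output) is compared with the reference on the
failure-difference scale:

```
diff = F̂ₓ(t) − F̂_ref(t),   SE(diff) = √(GSEₓ² + GSE_ref²),   z_m = (diff − δ_m)/SE(diff)
```

where the margin `δ_m = m · F̂_ref(t)` converts an *m*-fold relative risk
increase (20% and 100%) into an absolute failure excess.  With the two-sided
95% Wald interval (L, U) of the difference:

* **non-inferior** — U ≤ δ₂₀;
* **inferior at 100%** — L > δ₁₀₀;
* **inferior at 20%** — L > δ₂₀ (but not δ₁₀₀);
* **inconclusive** — the interval straddles the margin.

A sensitivity (historic) mode pins the reference at 3, 5 and 7 years to the
construct selected at 10 years.

## Worked example

The estimator on a five-subject toy sample (event at year 1, censored at 2,
event at 4, censored at 6 and 7):

```python
>>> from implantbench import km_failure_at
>>> est = km_failure_at([1.0, 2.0, 4.0, 6.0, 7.0],
...                     [True, False, True, False, False], 5.0)
>>> print(f"F(5) = {est.failure:.4f}  SE = {est.greenwood_se:.4f}  "
...       f"95% CI [{est.ci_low:.4f}, {est.ci_high:.4f}]")
F(5) = 0.4667  SE = 0.2483  95% CI [0.1369, 0.9317]
```

F(5) is the hand product-limit value 1 − (4/5)(2/3) = 0.4667: by year 5 an
estimated 46.7% of implants have been revised.  The interval is the
complementary log-log interval, asymmetric as failure intervals should be.

A full synthetic run from the shell:

```bash
$ cat sim.yaml
seed: 7
n_constructs: 500
size_law: {pareto_exponent: 1.5, max_size: 30000}
$ implantbench simulate --config sim.yaml --out registry.csv --truth-out truth.csv
wrote 112717 procedures (500 constructs) to registry.csv
$ implantbench analyze --registry registry.csv --out results
112717 parsed, 112717 retained, 0 zero-follow-up dropped
25 stratum/horizon cells analysed, 11 skipped; wrote 28 files to results
$ head -2 results/counts.csv
stratum,horizon_years,n_eligible,n_non_inferior,n_inconclusive,n_at_least_20_inferior,n_of_which_100_inferior,reference,reference_failure_pct
women 55-75,3.0,15,1,10,4,4,CoP stem-0326/cup-0326,0.28
```

Read: among women aged 55–75 at 3 years, 15 constructs had ≥ 500 procedures
at risk; the benchmark construct had 0.28% estimated failure; 4 constructs
were inferior to it by at least 20% relative risk (all 4 by at least 100%),
1 was non-inferior and 10 were inconclusive.  `implantbench report
--results results` then renders forest-plot CSVs and figures per cell.
Skipped cells (strata without any construct reaching 1000 at risk — typical
for the youngest patients at long horizons) are listed in `skipped.csv`.

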