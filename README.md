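# lossaver

An end-to-end analysis pipeline linking age, loss aversion and cortical
structure, built around a prospect-theory model of mixed-gamble choices:

- **task_design** — the 16 x 16 gain/loss grid ($10–40 gains in $2 steps,
  $5–20 losses in $1 steps) and seed-reproducible, level-balanced 128-trial
  designs.
- **choice_model** — power-utility subjective value with loss-aversion weight
  λ, curvature ρ and logit sensitivity τ; softmax acceptance probabilities;
  trial-level choice and reaction-time simulation.
- **cleaning** — the two-stage quality procedure: strict sub-200 ms trial
  filtering and a per-subject preference-consistency screen (acceptance must
  increase with gain, decrease with loss, increase with expected value).
- **hbayes_fit** — hierarchical Bayesian estimation of (λ, ρ, τ) with a
  custom adaptive MCMC sampler (per-subject Hamiltonian updates with analytic
  gradients, conjugate group-mean draws, collective-mode moves), R-hat/ESS
  diagnostics via arviz, a multi-start per-subject ML oracle, and posterior
  predictive checks.
- **neuro** — cortical-thickness table ingestion, parametric empirical-Bayes
  scanner harmonization that preserves age-related variance, and
  volume-weighted ROI construction (insula, OFC, ACC, PCC, whole brain).
- **stats** — demographic covariate screens, hierarchical linear-vs-quadratic
  age regression with nested F test and vertex age, per-ROI GLMs with
  Holm–Bonferroni correction, age-thinning fits, quasi-Bayesian causal
  mediation (ACME/ADE with percentile intervals), and age-split correlations.
- **synthetic_data** — a structural generator producing complete synthetic
  studies (trials, thickness tables, demographics) with known ground truth
  for the quadratic age–λ trajectory and the mediated share routed through
  PCC thickness.

## Command line

All stages are exposed through one CLI:

```bash
lossaver simulate-design --n-trials 128 --seed 1 --out design.csv
lossaver simulate --design design.csv --lambda 1.58 --rho 0.60 --tau 3.07 \
    --seed 2 --out trials.csv
lossaver clean --in trials.csv --out clean.csv --report report.json
lossaver fit --in clean.csv --chains 4 --seed 1 --out-dir fits/
lossaver harmonize --in thickness.csv --out harmonized.csv
lossaver rois --in harmonized.csv --out rois.csv
lossaver analyze --estimates fits/estimates.csv --rois rois.csv --out-dir results/
lossaver mediate --in merged.csv --n-sims 1000 --seed 1
lossaver synth --n-subjects 106 --seed 1 --out-dir data/
```

`lossaver synth` emits exactly the CSV schemas the rest of the pipeline
consumes, so `synth -> clean -> fit -> harmonize -> rois -> analyze ->
mediate` runs with no external data.

## Notes

- Reaction-time filtering keeps trials at exactly 200 ms (the criterion is
  strictly "< 200 ms").
- The hierarchical sampler flags its result (and warns) whenever any
  hyperparameter R-hat exceeds 1.1; at default settings (4 chains, 1000
  warmup + 1000 draws) large cohorts may need more draws to converge —
  `MCMCConfig(n_warmup=1200, n_draws=2000)` converges comfortably at
  40 subjects x 128 trials.
- `reproduction_mode=True` in the regression functions switches from
  mean-centered age and dummy-coded covariates to raw age and the original
  numeric covariate coding.
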