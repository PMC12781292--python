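# cfmdnet

Dose-response and symptom-network modelling of **compassion fatigue (CF)**
and **moral distress (MD)** in ICU nurses.

ICU nurses are chronically exposed to suffering and to ethical conflicts they
cannot always act on. Two occupational hazards result: compassion fatigue — a
depletion of emotional resources from empathetic engagement with traumatised
patients — and moral distress — the strain of knowing the right action but
being prevented from taking it. This package implements a two-pronged
analysis of how the first drives the second:

1. **Dose-response.** MD (from the 22-item Moral Distress Scale-Revised,
   per-item frequency × intensity summed, range 0–352) is regressed on CF
   (a ProQOL composite: burnout + secondary traumatic stress + reverse-scored
   compassion satisfaction, range 30–150) with a 4-knot restricted cubic
   spline. With knots t₁<t₂<t₃<t₄, the spline contributes x plus two
   truncated-power terms constrained to be linear beyond the boundary knots;
   a joint F-test of the two nonlinear coefficients tests nonlinearity, and
   the interquartile contrast of predicted MD (with a Wald z-interval)
   summarises the total effect. An unadjusted model and a covariate-adjusted
   model (gender, age band, tenure, education, title, income, income
   satisfaction) are both supported, as is the a-priori power machinery
   (noncentral-F minimum n, participants-per-node heuristic).

2. **Symptom network.** Every item becomes a binary node (MD item active iff
   its frequency × intensity product is nonzero; CF item active iff the raw
   response exceeds "never"), giving a 52-node two-community network. An
   Ising model P(x) ∝ exp(Σᵢ τᵢxᵢ + Σᵢ<ⱼ ωᵢⱼxᵢxⱼ) is estimated by nodewise
   L1 logistic regression with EBIC selection and AND-rule symmetrisation.
   Four bridge-centrality indices (bridge strength, expected influence,
   closeness, betweenness) quantify cross-community connectivity, with a
   case-dropping bootstrap and CS coefficient for stability. In-silico
   interventions then shift each CF node's threshold τ by ±2 SD of all
   thresholds (alleviating/aggravating), simulate 5,000 observations per
   scenario by single-site MCMC, and rank CF symptoms by the induced change
   in the mean MD sum score (Welch t-tests, Benjamini-Hochberg FDR).

The original survey data are not public, so a **synthetic-cohort module**
generates data with the same statistical structure — reported covariate
marginals, a saturating CF→MD curve that rises steeply around CF 60–90, and
a two-community Ising truth with explicitly planted bridge nodes — allowing
every stage to be validated by parameter- and target-recovery.

## Worked example

```python
from cfmdnet.synthetic import CohortSpec, simulate_dose_response_cohort
from cfmdnet.dose_response import (fit_rcs_model, nonlinearity_test,
                                   total_effect, PowerSpec,
                                   required_sample_size_f2, heuristic_network_n)

cohort = simulate_dose_response_cohort(CohortSpec(seed=1))   # n = 645
fit = fit_rcs_model(cohort.md_total, cohort.cf_total, cohort[["gender"]])
F, p = nonlinearity_test(fit)
est, se, ci = total_effect(fit)
print(f"R^2 = {fit.rsquared:.3f}; nonlinearity F = {F:.2f}, p = {p:.2e}")
print(f"total effect = {est:.2f} (SE {se:.2f}, CI {ci[0]:.2f}-{ci[1]:.2f})")
print(required_sample_size_f2(PowerSpec()), heuristic_network_n(52))
```

prints

```
R^2 = 0.445; nonlinearity F = 25.72, p = 1.80e-11
total effect = 43.61 (SE 3.11, CI 37.51-49.71)
254 (520, 578)
```

i.e. the synthetic cohort shows a strongly nonlinear dose-response (the
F-test rejects linearity), moving from the 25th to the 75th CF percentile
raises predicted MD by ≈ 44 points, a regression power analysis
(f² = 0.10, α = 0.05, power 0.95, 10 predictors) needs 254 participants, and
the 10-per-node network heuristic needs 520 (578 after 10% attrition).

On the network side:

```python
from cfmdnet.synthetic import NetworkTruthSpec, make_ground_truth_ising
from cfmdnet.nira import run_scenarios, identify_core_targets

model, part = make_ground_truth_ising(NetworkTruthSpec(seed=1))
res = run_scenarios(model, part, "alleviating", n_sim=5000, seed=42)
print(identify_core_targets(res))
```

recovers the planted dominant bridge: the only significant alleviating
target is CF26 (mean MD 7.18 vs baseline 7.52, Δ = −0.34, t = −7.05,
FDR-adjusted p < 0.001).

A `cfmdnet` CLI wraps the same functions (`cfmdnet simulate-cohort`,
`dose-response`, `network-estimate`, `network-sample`, `bridges`,
`stability`, `nira`, `pipeline`); `cfmdnet pipeline --config config.yaml`
runs every stage end-to-end with per-stage seeds and writes CSV/JSON/PNG
artifacts.

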