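# Methods

## Instruments and composites

The ProQOL administers 30 items on a 1–5 Likert scale in three 10-item
subscales: compassion satisfaction (CS), burnout (BO), and secondary
traumatic stress (STS). The compassion-fatigue composite sums BO and STS as
administered and the CS items after reversal (6 − x), so that every
component points toward resource depletion; the composite spans 30–150.
The MDS-R administers 22 items with paired frequency (0–4) and intensity
(0–4) ratings; the composite is the sum of per-item products, 0–352.

For the network, items are dichotomised: an MDS-R node is active iff its
frequency × intensity product is nonzero; a ProQOL node is active iff the
raw response exceeds 1 ("never"). CS items are dichotomised on the **raw**
administered response, not the reversed value — the activation rule is
phrased in terms of the administered anchors, and an "active" CS node then
means "experiences satisfaction at least rarely". Because the convention is
genuinely ambiguous, a switch (`reverse_cs_before_dichotomizing`) applies
the reversal to the CS columns first for callers who prefer
depletion-oriented activation semantics.

The mapping from node labels CF1..CF30 to subscale items is configurable;
the default composite ordering places CS at positions 1–10, BO at 11–20,
and STS at 21–30, which puts the classically bridge-prone BO/STS items in
the CF25–CF30 label range. Exact item text is configurable metadata because
the instrument is licensed.

## Dose-response model

MD is regressed on a restricted cubic spline of CF (4 knots at the 0.05,
0.35, 0.65, 0.95 quantiles of the **predictor** — the conventional default
placement). The truncated-power construction is used, with the two
nonlinear columns scaled by (t₄ − t₁)² so all three spline coefficients are
on a comparable scale. Model 1 is unadjusted; Model 2 adds dummy-coded
categorical covariates (first category = reference). Estimation is ordinary
least squares (statsmodels); nonlinearity is a joint F-test of the two
nonlinear coefficients; the total effect is the 25th→75th-percentile
contrast in predicted MD with a delta-method SE and a z-quantile (1.96)
Wald interval — the z convention is fixed so intervals match the
estimate ± 1.96·SE arithmetic exactly. Standardised coefficients come from
refitting after z-scoring both MD and CF.

Power utilities: the minimum n for the overall regression F-test uses the
noncentral-F distribution with noncentrality λ = f²·n and df (p, n−p−1),
scanning n upward; the network heuristic is 10 participants per node with a
ceiling-inflated target for anticipated attrition.

## Ising model

The model lives on {0,1}ⁿ (not ±1): P(x) ∝ exp(Σ τᵢxᵢ + Σᵢ<ⱼ ωᵢⱼxᵢxⱼ),
whose full conditionals are logistic regressions — τ is the logistic
intercept and ω the coupling matrix. Exact enumeration (≤ 20 nodes) serves
as the oracle for sampling and interventions on small models.

Sampling draws each observation from an independent chain: uniform-random
0/1 initialisation, then (default) 100 sequential full sweeps in which each
node is redrawn from its conditional. For single-site 0/1 updates the
Gibbs draw coincides with the Metropolis-Hastings acceptance rule. Chains
are vectorised across observations (each row only ever sees its own state),
which preserves between-observation independence — required for the
downstream t-tests — while keeping 5,000-observation scenarios under a
second on one CPU.

Estimation follows the eLasso recipe: per node, an L1-regularised logistic
regression on all other nodes over a 100-point penalty path (log-spaced
from the max-score penalty to 1% of it), per-node penalty selected by
EBIC(γ = 0.25) with the nonzero-neighbour count as the complexity term;
edges are AND-rule symmetrised (present only if both directions select it,
value = the mean of the two directed coefficients; OR rule available).
liblinear is used with a large intercept scaling (so the intercept is
effectively unpenalised) and a fixed internal shuffle seed for exact
reproducibility. A plain maximum pseudo-likelihood mode (unpenalised
nodewise fits) is available for small dense problems and for fast
bootstrap studies.

## Bridge centrality

Bridge strength is Σ|ωᵢⱼ| over the other community; bridge expected
influence is the signed version (so |EI| ≤ strength always). Geodesics use
edge length 1/|ω| — strong associations are short — giving bridge closeness
as the reciprocal mean distance to the other community's (reachable) nodes,
0 when none are reachable, and bridge betweenness as the count of
cross-community geodesics passing through the node as an intermediate, with
tied geodesics splitting credit equally. Rankings break ties by node label.

## Stability

The case-dropping bootstrap re-runs the estimate→bridge pipeline on
subsamples retaining (1 − f)·n cases (default grid f = 0.05..0.75 in steps
of 0.05, 500 bootstraps; both configurable) and Spearman-correlates each
subsample index vector with the full-sample one (Pearson available). The CS
coefficient of an index is the largest f at which ≥ 95% of correlations
stay ≥ 0.7; > 0.5 reads "strong", 0.25–0.5 "acceptable" (both endpoints
inclusive), < 0.25 "poor". Subsamples in which estimation fails (e.g. a
node with no variance left) are recorded as missing rather than raised.

## In-silico interventions

One scenario perturbs one CF node's threshold by k·s, with k = 2 by default
and s the sample SD (n−1 denominator) of **all** estimated thresholds;
alleviating subtracts, aggravating adds. Per direction this yields 1
baseline + one scenario per CF node (31 scenarios for a 30-node CF
community), each freshly simulated with its own sub-seed at n_sim = 5,000
observations. The outcome is each observation's MD-community sum score;
scenarios are compared with baseline by Welch t-tests (perturbation changes
the outcome variance, so pooled variances are not assumed), BH-FDR adjusted
within each direction, and significant scenarios ranked by |Δ mean MD|.

## Synthetic cohorts

Covariates are sampled independently from the reported marginal category
frequencies of the 645-nurse study population (joint distributions were not
reported). CF totals are a truncated normal on [35, 139] with location 82
and scale 17.8 (IQR/1.349), matching the reported median, IQR, and range.
MD given CF follows a 4-parameter logistic curve (lower plateau 25, upper
plateau 110, midpoint 75, scale 8) — steepest around CF 60–90 and flat at
the extremes — plus additive covariate shifts (default: +8 for female,
other effects 0, mirroring gender being the only significant covariate) and
Gaussian noise (SD 30, giving an R² in the 0.3–0.5 range at n = 645),
truncated to [0, 352]. A "linear" curve option (intercept 60, slope 0.8,
chosen so truncation is negligible over the CF range) provides the null for
calibration studies of the nonlinearity test.

The network ground truth plants two communities (22 MD + 30 CF nodes) with
positive intra-community couplings sprinkled at density 0.15 with weights
uniform on (0.3, 0.9), cross-community couplings given **exactly** by an
explicit bridge list (default: CF26 dominant with edges 1.8 and 1.2 to
MD10/MD5, plus weaker bridges at CF28/CF25/CF29), and thresholds uniform on
(−3.5, −0.5). The threshold range is chosen so that node activations sit on
the informative part of the logistic rather than saturating: it roughly
balances the positive coupling input (moderate prevalences) and gives the
±2·SD threshold perturbation (≈ ±1.73) real leverage, so planted bridges
produce clearly detectable MD changes — the regime in which intervention
ranking is meaningful. Weight magnitudes are in the range typically printed
for estimated binary symptom networks. Item synthesis inverts
dichotomisation (inactive CF → 1, active CF → uniform 2–5; inactive MD →
frequency 0, active MD → frequency and intensity uniform 1–4), so
dichotomising the synthesised items reproduces the binary matrix exactly.

What the generator does **not** emulate: ordinal item dependence beyond the
binary level, covariate–network dependence, item-level measurement error,
and any particular empirical coefficient values. Passing recovery tests
therefore shows the pipeline is correct and calibrated under the assumed
structure, not that real survey data satisfy that structure.

## Numerical choices and problem sizes

- Enumeration is capped at 20 nodes (2²⁰ states); larger models must be
  sampled.
- Knot placement refuses tied quantiles and directs the caller to manual
  knots; rank-deficient design matrices are rejected with the collinear
  columns named.
- Determinism: every stochastic routine takes a seed; scenario and
  bootstrap sub-seeds are spawned from a root SeedSequence, so whole
  pipeline runs are byte-reproducible.
- Default problem sizes used in the test suite (n = 645 cohorts, n = 1,000
  binary samples, 5,000-observation scenarios, 1,000-replicate calibration,
  40–500 bootstraps) were chosen so each property is tested at the scale
  the method is meant for while the full suite stays in the one-minute
  range on a single CPU.

## Limitations

- Cross-sectional logic throughout: intervention simulations rank nodes by
  model-implied influence, not by causal evidence.
- Only two communities are supported by the bridge indices; multi-community
  extensions are out of scope.
- No missing-data handling: the scoring layer requires complete item
  responses (the motivating survey design enforced completeness).
- The eLasso estimator's settings (γ, path, rule) are documented defaults;
  correctness is defined by recovery on synthetic truths, not by
  replication of any particular empirical network.
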