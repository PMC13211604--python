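# Methods

`vhhrisk` implements the computational chain of an urban volatile-halogenated-
hydrocarbon (VHH) monitoring campaign: composition and background-enhancement
statistics, uncertainty-weighted positive matrix factorization (PMF) for
source apportionment, deterministic and probabilistic inhalation risk
assessment with replicated Monte-Carlo convergence diagnostics, and Sobol
total-order sensitivity analysis. A synthetic-campaign generator with planted
ground truth stands in for raw canister data, which are not publicly
deposited.

## Units and conversions

Observations are mixing ratios in pptv; the risk equations need mass
concentrations in μg m⁻³. Conversion uses

    c [μg m⁻³] = x [pptv] · MW [g mol⁻¹] / (V_m [L mol⁻¹] · 1000)

with the molar volume V_m defaulting to 24.45 L mol⁻¹ (25 °C, 1 atm). The
convention is exposed as a parameter because monitoring programmes differ
between 20 and 25 °C; per-sample temperature/pressure corrections are out of
scope.

## Species registry

The packaged fixture covers the campaign's 14 retained species — 6 Montreal-
Protocol-regulated CFCs/ODSs (bromomethane is grouped with the regulated set
despite its short lifetime, as it is Protocol-controlled) and 8 unregulated
chlorinated very short-lived substances (VSLSs). Each record carries
molecular weight, atmospheric lifetime, ODP, GWP₁₀₀, a representative method
detection limit (MDL, within the analytical method's 2–17 pptv range), the
concurrent Northern-Hemisphere background where a station record exists, the
campaign mean ± SD mixing ratio, and toxicity values. Inhalation unit risks
(IUR, per μg m⁻³) and reference concentrations (RfC, mg m⁻³) are not part of
the campaign data; they are taken from IRIS, with OEHHA chronic RELs where
IRIS has none, and one provisional HEAST-style RfC for 1,1-dichloroethane.
Each value's source is noted in the fixture file. 8 species carry an IUR and
10 an RfC; species without a value are simply excluded from the respective
risk sums.

## Descriptive statistics

* Composition shares are computed on means-of-samples (each species' share of
  the grand total of per-species means), matching the standard campaign
  presentation, not as averaged per-sample shares.
* The detection filter retains species detected — above MDL and non-missing —
  in strictly more than 60% of samples (strict inequality; missing values
  count as non-detections).
* Diurnal profiles report per-window means/SDs plus the SD across window
  means (sample SD, ddof = 1), the amplitude statistic used to call a cycle
  flat or U-shaped.
* Correlations are pairwise Pearson R with two-sided p-values from the
  t-transform, unadjusted for multiple testing; zero-variance pairs are
  reported as undefined (NaN), never as a number.
* Background enhancement is `observed − background` (pptv) and
  `100·(observed − background)/background` (%). Values are always computed
  from the inputs; no published enhancement numbers are stored, so rounding
  of the published inputs can shift the last printed digit (e.g. carbon
  tetrachloride's rounded mean and background imply +14 pptv where the
  original unrounded data gave +13 pptv).

## PMF receptor model

The sample × species matrix X is decomposed as X ≈ G·F with G (samples ×
factors) and F (factors × species) nonnegative, minimizing the weighted
objective

    Q = Σᵢⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ)².

Uncertainty preparation follows receptor-model practice: missing cells are
imputed with the species median and down-weighted with u = 4 × median
(configurable; no standard exists for imputed-cell uncertainty); values below
the MDL are replaced by MDL/2 with u = (5/6)·MDL; quantified values get
u = sqrt((0.1·c)² + MDL²), with the 0.1 error fraction configurable as a
scalar or per-species vector.

The solver uses weighted multiplicative updates, which are monotone in Q
(each iteration cannot increase Q; the test suite asserts this on the full
trace), with multi-start over random nonnegative initializations (default
20), ties broken toward the lowest start index, convergence at a relative Q
change below 1e-8, and entries floored at 1e-12 to keep the multiplicative
updates alive. The reported F is row-normalized (profiles sum to 1) with G
rescaled to carry the mass. Q_expected = n·m − p·(n+m) is reported as a
diagnostic only; the factor count is user-specified. No rotational (Fpeak)
exploration is performed.

Factor contributions are each factor's share of total reconstructed mass;
species profile percentages split each species' mass across factors (rows
sum to 100%). Because PMF is identifiable only up to permutation and scale,
recovered factors are matched to reference profiles by Hungarian assignment
on cosine similarity of the profile rows (scale-invariant).

### Rotational indeterminacy of a near-constant factor

A structural caveat, verified on the synthetic campaign: when one factor's
contribution series is nearly constant (here the CFC-bank factor, whose
stability is exactly what the long CFC lifetimes produce), the transform
G′ = G·T⁻¹, F′ = T·F that moves constant bank mass into the varying factors
leaves Q exactly unchanged and stays nonnegative up to a capacity bound set
by the varying factors' peak-to-mean ratios. Multistart fits that agree on Q
to machine precision can therefore disagree on the bank factor's mass share
by several percentage points, while the profiles themselves remain well
identified (cosine ≥ 0.98). On the default synthetic campaign the planted
profiles are recovered essentially exactly, and the three industrial shares
to within ~3 points, but the bank share carries an irreducible indeterminacy
of roughly ±2–5 points. Any published contribution share for a near-constant
source estimated with an unconstrained PMF carries the same indeterminacy.

## Synthetic campaign generator

The generator emulates a short summer campaign in an industrial basin city:
7 sampling days × 7 daylight windows (08:00–20:00 starts at 2 h spacing,
49 samples), 14 species, and a 4-source latent structure — CFC-bank leakage,
industrial process emissions, solvent use, and electronics-industry cleaning
agents with planted mass shares 19.9 / 27.8 / 23.7 / 28.6%.

Every sample satisfies X = (G_true · F_true) ∘ N exactly, with N mean-one
multiplicative lognormal noise (default fraction 0.1; regulated CFCs get
0.2× that, reflecting their higher measurement precision at the top of the
calibration range), so PMF recovery can be scored against ground truth.
Specifics:

* **Profiles.** A qualitative allocation seed (fraction of each species'
  mass per source, with exact zeros: the bank source carries only CFCs, and
  each industrial source has at least one exclusive species) is polished by
  iterative proportional fitting to match the default species means and the
  planted shares exactly. The zeros are deliberate: without sparsity in F
  and near-zero excursions in G, exact nonnegative factorizations are
  non-unique and no solver could recover the planted factors.
* **Species means.** VSLS means are campaign-scale round numbers chosen so
  each industrial source has its own dominant species mass; CFC means keep
  the relative abundances of the campaign summary table, scaled so the CFC
  total equals the planted bank share (the bank source carries only CFCs, so
  the budget must balance). The published campaign's composition statistics
  are therefore exercised on the fixture's summary moments, not on the
  synthetic campaign.
* **Temporal structure.** Source activities are mean-one lognormal series:
  sigma 0.015 for the bank source (CFC columns come out with CV ≈ 2–3%,
  mirroring the near-constant regulated species) and 0.8 for the industrial
  sources (species CVs up to ≈ 1, as in real urban VSLS records). The three
  industrial sources are modulated by distinct mean-one diurnal multiplier
  vectors with morning/evening peaks and a pronounced mid-afternoon minimum
  (boundary-layer dilution); the bank source is flat. Window draws are
  independent — within-day autocorrelation beyond the diurnal shape is not
  modelled.
* **Tracer.** A CO series is generated as a baseline plus coupling to the
  source carrying most chloromethane, plus 5% noise; the chloromethane–CO
  correlation exceeds 0.5 for every tested seed. Weekday/weekend source
  switching is not simulated.
* **Censoring.** Values below the species MDL are kept in the truth but
  flagged, so the below-MDL substitution rules can be exercised; at the
  default concentration scales censoring is rare.
* All draws derive from one `numpy` Generator seeded from the config, so
  every output is byte-reproducible.

The separate PMF test-case generator plants a random Dirichlet profile
matrix with one exclusive marker species per source, lognormal contributions
with a 25% source-off fraction (both identifiability anchors), multiplicative
noise, and uncertainties from the proportional-error rule with synthetic
MDLs at 5% of each species' mean.

What passing tests on these synthetics do **not** show: robustness to
meteorology-driven covariance, instrument drift, sample autocorrelation, or
profile overlap beyond what is planted.

## Deterministic risk model

    EC  = CA · ET · EF · ED / AT        exposure concentration, μg m⁻³
    LCR = EC · IUR                      lifetime cancer risk
    HQ  = EC / (RfC · 1000)             hazard quotient
    HI  = Σ HQᵢ                         hazard index

Defaults are the resident-adult values ET = 24 h d⁻¹, EF = 365 d a⁻¹,
ED = 74.8 a, AT = 74.8·365·24 h, under which the time factor cancels and
EC = CA exactly. Classification: LCR < 1e-6 negligible, 1e-6 ≤ LCR ≤ 1e-4
potential, > 1e-4 definite concern (the 1e-6 boundary is included in the
potential band — a documented choice; the guidance documents do not specify
it); HQ/HI ≤ 1 negligible, > 1 potential non-carcinogenic risk. Cumulative
cancer risk is the plain sum of per-species LCRs.

With the fixture's campaign means and IRIS/OEHHA toxicity values the model
reproduces the campaign's qualitative findings — the same four chlorinated
species (1,2-dichloroethane first) exceed the 1e-6 level, the same four fall
below it, and the HI contribution ordering is trichloroethylene >
1,2-dichloropropane > chloromethane > bromomethane. Absolute point risks are
*not* reproduced: the campaign's published values rest on unprinted unit-risk
values and distribution conventions, and this package reports its own
computed values rather than tuning to match.

## Distribution fitting and selection

Candidate families are point, uniform, triangular, normal and lognormal,
fitted by maximum likelihood (lognormal: mean/SD of logs, MLE ddof = 0;
uniform/triangular: range plus a moment-based mode). Goodness of fit uses the
Anderson–Darling statistic

    A² = −n − (1/n) Σᵢ (2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))]

with CDF values clamped to (1e-12, 1−1e-12) under a warning. Family selection
minimizes the raw A² statistic rather than a p-value, because composite-
hypothesis critical values differ by family while the statistic ranks fits on
a common footing; Stephens-corrected p-value tables are out of scope. Values
below the MDL are replaced by MDL/2 before fitting (configurable).

## Replicated Monte Carlo

The risk chain is propagated through `n_rep` = 100 independent replications
of `n_iter` = 10,000 draws. Input distributions: concentrations lognormal,
moment-matched (σ² = ln(1+(sd/mean)²), μ = ln mean − σ²/2) to the campaign
mean/SD per species; ET and EF point values (continuous residential
exposure); ED normal (74.8 a, 10% CV) truncated to (0, 100]; IUR/RfC point
values. These exposure distributions are assumptions, not campaign data, and
every one can be overridden. By default AT is derived as ED·365·24 within
each draw (fully correlated with ED, which therefore cancels from the
chain); an independent-AT mode exists for sensitivity experiments.
Concentrations are drawn independently across species — no cross-species
correlation model is available.

Convergence diagnostic: MCE is the standard deviation of the replication
means; SD is the *minimum* within-replication standard deviation (the
conservative reading — it inflates the ratio); the ratio 100·MCE/SD must
fall below 5%. A zero SD leaves the ratio undefined and is reported as such.
Spreads below 1e-12 of the output mean are treated as exactly degenerate
(floating-point summation noise otherwise manufactures a meaningless ratio).
Sampling is inverse-CDF from per-replication substreams spawned from one
master seed, so results are bit-reproducible and early replications are
unchanged when `n_rep` grows. Summaries (mean, median, 95th percentile by
linear-interpolation quantile) pool all replications. At these sizes the
ratio lands near its theoretical ≈ 1/√n_iter = 1% and scales accordingly.

## Sobol sensitivity

Total-order indices use the Saltelli block design (base blocks A and B plus
one column-swapped block per input) with the Jansen estimator

    S_Tᵢ = (1/2N) Σ (f(A) − f(A_B⁽ⁱ⁾))² / Var(f),

Var taken over the combined base evaluations. When N is a power of two the
base sample is a scrambled Sobol' sequence; otherwise plain pseudo-random
sampling. Inputs are treated as independent (no copula). Standard errors
come from the per-row spread of the Jansen summand. Negative estimates
(Monte-Carlo noise around zero) are reported raw with their standard error,
never clipped; estimates below −0.05 trigger a warning. A single-input model
returns S_T = 1 directly without sampling. Rankings are descending by S_T
with exact ties broken alphabetically.

For the cancer-risk chain the sensitivity runs hold AT at its point value so
that ED variance propagates. Two regimes are exercised: for wide-CV species
(e.g. 1,2-dichloroethane, CV ≈ 1) the concentration dominates the output
variance; for a narrow-CV species with a comparatively small unit risk
(carbon tetrachloride) the time-activity parameters take over. These are
qualitative reproductions; the exact input distributions behind the
campaign's published rankings are not printed anywhere.

## Pipeline

`run_pipeline` executes detection filter → descriptive statistics → PMF →
deterministic risk → distribution fitting → Monte Carlo → Sobol, each stage
seeded deterministically from the global seed and the stage name, and writes
a manifest recording per stage the seed, the input hash and a content hash of
every artifact; re-running an identical configuration reproduces every hash.
A stage failure aborts downstream stages and leaves a structured error entry.
The `vhh` CLI exposes the stages as subcommands; the numbered scripts under
`analysis/` run the same library code as a narrative sequence.

## Problem sizes

Default analysis sizes — 49-sample campaigns, 20-start PMF fits, 100 × 10,000
Monte-Carlo draws, Sobol base samples of 2¹³–2¹⁵ — were chosen so that every
statistic sits comfortably inside its sampling tolerance while the full
pipeline, test suite and reproduction script each run in minutes on a single
core.
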