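# Methods

## Structural model

The model tracks 15 states per subject: bone-marrow precursors `PRE`, two
tolerance trackers `TOL_1, TOL_2`, four reticulocyte pools (immature/mature
x marrow/blood), four erythrocyte transit compartments `RBC_1..4` and four
hemoglobin compartments `Hb_1..4`.  Internal units are days, 1e9 cells/L on
the reticulocyte side, 1e12 cells/L on the erythrocyte side, pg per cell for
MCH and g/L for hemoglobin; the single conversion constant 1e-3 maps
reticulocyte-side fluxes onto the erythrocyte scale and (cells x pg) onto
g/L.

Homeostasis closes the model: every rate constant and the full initial
state follow analytically from the observable baselines,

* `k_PRE = 1/LS_PRE`, `k_RBC = n_CTR/LS_RBC`,
* `k_RET = k_RBC (RBC_0/n_CTR) / (RET_0 (1 - IRF_0))` (flux balance between
  the reticulocyte and erythrocyte sides),
* `p_release = IRF_0/(1 - IRF_0)` so that blood IRF at equilibrium equals
  `p/(1+p) = IRF_0`,
* baseline flux `F_0 = k_RBC RBC_0 / n_CTR`, precursor pool
  `PRE_0 = F_0 LS_PRE`, `Hb_0 = RBC_0 MCH_0`.

The steady state is exact (the right-hand side evaluates to ~1e-15 at it),
so drug-free simulations of any length sit on the baselines to solver
tolerance; this is asserted in the test suite rather than assumed.

### Feedback

A fractional hemoglobin deficit produces a stimulation factor
`S = exp(γ (Hb_0 - Hb_tot)/Hb_0)` acting multiplicatively on precursor
recruitment (`R_in = F_0 · S · M`) and on reticulocyte kinetics.  Two
choices here were genuinely open:

* **Sign.** The published footnote form of the exponent has the opposite
  sign, which with γ = 2.42 would *suppress* recruitment when hemoglobin
  falls, contradicting the accompanying description of the feedback as
  stimulating recruitment on a deficit.  The deficit-stimulates orientation
  is the default; the literal footnote sign is available as
  `feedback_deficit_stimulates: false`.
* **Placement on the reticulocyte chain.** The feedback on `k_RET` is
  described as allowing *earlier and faster release of immature and mature
  reticulocytes from the bone marrow into blood*.  We therefore scale the
  bone-marrow exit rates (the outflows of the two marrow pools) by `S`,
  leaving blood-side maturation at `k_RET`.  This matters: if `S` scaled
  every reticulocyte rate uniformly, it would cancel out of the standing
  blood count (count = flux/rate, both scaled), so silencing-then-releasing
  the feedback could never produce the characteristic post-cessation
  reticulocyte spike, and an inhibited recruitment rate could never show
  the observed in-treatment recovery toward baseline.  With marrow-exit
  placement both behaviors emerge.  The uniform variant remains available
  (`ret_feedback: "uniform"`) for sensitivity analysis.

### Tolerance

`TOL_1, TOL_2` are first-order trackers of `PRE` (rate `k_TOL`, initialized
at `PRE_0`); recruitment is modulated by `M = PRE_0/TOL_2`.  At baseline
`M = 1`; sustained stimulation raises `PRE`, hence (after a ~2/k_TOL ≈ 90-day
lag) lowers `M`, emulating depletion of the stem-cell reservoir.  `TOL_2` is
floored at `1e-9 · PRE_0` with a logged warning; reaching the floor signals
numerically degenerate depletion, not a physiological regime.  With
`k_TOL = 0` the trackers freeze and `M ≡ 1`.

### Hemoglobin chain

The per-cell hemoglobin content of the erythrocyte compartments is
represented as hemoglobin *amounts* `Hb_n = RBC_n x MCH_n` with simple
transit.  A literal content chain (`MCH_n` states relaxing toward the
content of incoming cells) is identical at baseline but does not conserve
hemoglobin mass when cell counts change; the mass form is therefore the
default and the content chain is kept behind `hb_chain: content` for
sensitivity analysis.  Drug inhibition of hemoglobin synthesis scales the
content of cells entering `RBC_1` (factor `1 - I`), with no additional
maturation delay — consistent with the immediate MCH response — so under
sustained inhibition MCH relaxes to `MCH_0 (1 - I)` with transit-chain
kinetics regardless of what the counts do.

### Drug mechanisms

Exposure enters as a step in `AUC_ss` over the treatment window (no washout
kinetics: the compound's PK is out of scope), driving
`I = Imax · AUC_ss/(AUC50 + AUC_ss)`.  Mechanism A multiplies the
hemoglobin input by `1 - I`; B multiplies recruitment `R_in`; C multiplies
`k_PRE`; D combines A's effect with `S ≡ 1` during the window (full
feedback silencing — both the recruitment and release arms share one
feedback term, and the reported steady counts under D require both to be
silenced).

## Statistical model

IIV is log-normal, `p_i = p · e^η`, `ω² = ln(1 + CV²)`, with default CVs
(%) of 28.02 (LS_RBC), 26.02 (RET_0), 5.34 (RBC_0), 4.82 (MCH_0), 32.09
(IRF_0) and 49.50 (AUC50); correlations default to identity (none were
reported) but any PSD correlation matrix can be supplied.  Residual error
is additive (RBC 0.18e12/L, MCH 0.35 pg), proportional (RET 0.22) or
combined (IRF: 0.96 percentage points additive + 0.38 proportional, kept on
the fraction scale internally as 0.0096).  Negative simulated observations
are retained by default to keep the error model honest (`truncate_at_zero`
clips them).

## Synthetic trial generator

The generator emulates a placebo-controlled four-arm Phase-1 design:
placebo/10/30/60 mg once daily for 120 days plus 120 days follow-up,
n = 15/17/16/14, hematology at days {0, 7, 14, 28, …, 112, 119, 126, 140,
…, 238} (20 visits), endpoints RET/RBC/MCH/IRF fitted and Hb_tot held out
for external validation.  Since the compound's population PK is not
published, exposure uses an invented dose-proportional model
`AUC_ss = dose · c_exp · e^η` with `c_exp = 1.1 mg/L·h per mg` — chosen
once so the arms span ~0.67x/2x/4x the typical AUC50 (i.e. ~24 %, 40 % and
48 % pathway inhibition), qualitatively matching the reported
dose-dependence — and 30 %CV between-subject exposure variability, a
typical magnitude for AUC in healthy volunteers.  Hb_tot, not being fitted,
has no published residual spec; 3 g/L additive is this package's choice
(~2 % of baseline, plausible analyzer noise).  All subjects are male by
default (the female baseline offset is of unclear scale in the source and
is configurable); dropout is not modeled.

What the generator does *not* emulate: real assay drift, circadian or
posture effects, visit-window jitter, dropout/missingness, PK accumulation
and washout, or model misspecification — passing recovery tests therefore
demonstrates internal consistency of simulator + estimator, not performance
on real clinical data.

## Estimation

Full nonlinear mixed-effects machinery (SAEM/FOCE) is out of scope; the
package fits by:

* **Naive-pooled ML** — one typical parameter vector for all subjects,
  individual exposures from the data, Gaussian likelihood with combined
  variance `σ² = sd_add² + pred² sd_prop²` per endpoint.  Free parameters
  are optimized on log (positives) or logit (fractions) scales with box
  bounds by Nelder-Mead with restarts and seeded multi-start; default
  starts are data-driven (baseline means per endpoint, a literature-style
  lifespan of 120 d, unit feedback, median active exposure as the potency
  start), not the generating values.  `LS_PRE` (5 d) and `Imax` (0.6) stay
  fixed, mirroring the reference analysis.  An optional finite-difference
  Hessian provides asymptotic SEs and flags near-singular (practically
  non-identifiable) free sets, e.g. Imax and AUC50 jointly free at one dose
  level.
* **Two-stage** — independent per-subject fits aggregated as geometric mean
  (typical value) and log-scale SD → %CV (IIV).  Subjects that fail to
  converge are excluded (reported, threshold configurable); subjects whose
  estimate lands on a box bound are also excluded, because a boundary
  estimate indicates a flat likelihood direction — typically a
  near-saturated subject (`AUC_ss >> AUC50`, inhibition ≈ Imax) carrying
  almost no information about potency.  This exclusion slightly censors
  low individual AUC50 values and is the known cost of a desk-scale
  estimator relative to a mixed-effects fit.

Two properties worth knowing when interpreting fits: (i) with proportional
or combined error the ML optimum on noise-free data is *not* the generating
value — the prediction-dependent variance term rewards smaller predictions
(for a flat profile with proportional SD σ the optimum solves
`x(x-1) = σ²`, `x = obs/pred`, about −4.4 % at σ = 0.22); exact
self-recovery holds for additive error, which is what the corresponding
test asserts.  (ii) Hb_tot records are excluded from fitting by default and
reserved for held-out validation via the VPC machinery.

The simulation-estimation experiment used by the acceptance script runs at
the trial's own scale (62 subjects, full IIV and residual error): the
typical erythrocyte lifespan, baselines and feedback exponent come from the
pooled fit, while the half-maximal exposure comes from the two-stage fit of
the treated subjects — under 49.5 %CV potency IIV a pooled fit can only
estimate a population-averaged potency, whose sampling spread across trial
replicates is roughly twice that of the two-stage geometric mean.

## Simulation outputs

* Mechanism panels: one sampled population (IIV only, no residual error) is
  reused across mechanism x exposure scenarios; bands are per-time
  percentiles over subjects, by default 5/50/95 (median + 90 % prediction
  interval).  The reference panels use 2000 subjects; tests and examples
  use 500, which is enough for stable 5th percentiles of the endpoints at
  the reported thresholds.
* VPC: replicate trials (new individuals + residual error) under the
  observed design; bins are the nominal visit days; the observed 5/50/95
  percentiles are compared with (by default) 90 % confidence intervals of
  the simulated percentiles from 200 replicates.  Percentile levels and CI
  width are configurable; prediction-corrected VPCs are not implemented.

## Numerical choices

One vectorized right-hand side serves all stacked individuals (numba-jitted
when importable; an identical pure-numpy body otherwise).  Exposure is a
step, so integration is segmented at `t_on`/`t_off` with the inhibition
multipliers and the feedback switch precomputed per segment — exact
discontinuity handling with no event detection.  Single subjects integrate
with LSODA, stacked populations with RK45 (the system's fastest rate,
`k_RET · S ≲ 3/day`, keeps explicit stepping efficient); relative tolerance
is 1e-8 for reference runs and 1e-6 inside optimization loops, with
per-state absolute tolerances scaled from the initial condition.  Nelder-
Mead tolerances are `xatol = 1e-4` (transformed scale, ~0.01 % in a
parameter) with up to two restarts per start.

## Known limitations

* Pooled estimates inherit the usual naive-pooling biases (e.g. the typical
  baseline under proportional error, population-averaged potency under
  strong IIV); the package documents rather than corrects them — a proper
  mixed-effects estimator is future work.
* The tolerance functional form and the feedback's exact published
  implementation are partly empirical; extrapolation far outside the
  exercised exposure range (0.5x–4x AUC50) should be done with care.
* Iron metabolism, erythropoietin as an explicit state, reticulocyte
  hemoglobin content, transfusion/blood-loss modules and covariate models
  are out of scope.
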