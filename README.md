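# erythrosim

Semi-mechanistic population PKPD modelling of erythropoiesis and hemoglobin
synthesis.

`erythrosim` is for pharmacometricians and clinical pharmacologists who need
to ask *what happens to the red-cell system* when a drug inhibits one step of
it: hemoglobin synthesis, precursor recruitment, or precursor-to-reticulocyte
differentiation — with or without an intact homeostatic feedback.  The
package provides the structural ODE model, the statistical (population)
layer, a synthetic Phase-1-style trial generator, mechanism what-if
simulation with prediction intervals, visual predictive checks (VPCs), and
likelihood-based parameter estimation, all scriptable from Python or a CLI.

## The model

Cells flow through a chain of transit compartments:

```
R_in,PRE -> PRE -> RET_imm,BM -> (p_release)    -> RET_imm,BL \
                              -> (1 - p_release) -> RET_mat,BM -> RET_mat,BL
                                                -> RBC_1 -> RBC_2 -> RBC_3 -> RBC_4 ->
```

* Precursors (`PRE`) mature in marrow with transit time `LS_PRE = 1/k_PRE`
  (5 days, fixed).
* Reticulocytes occupy four pools — immature/mature x marrow/blood — all
  governed by one rate constant `k_RET`; a fraction
  `p_release = IRF_0/(1 - IRF_0)` is released prematurely into blood,
  reproducing the baseline immature reticulocyte fraction (IRF).
* Erythrocytes age through four transit compartments with
  `k_RBC = n_CTR/LS_RBC` (`n_CTR = 4`, lifespan `LS_RBC` ≈ 125 days); a
  parallel four-compartment chain carries their hemoglobin, so
  `Hb_tot = Σ_n RBC_n x MCH_n` and `MCH = Hb_tot / Σ_n RBC_n`.
* Homeostasis fixes every rate and initial condition from the observable
  baselines (`RET_0`, `RBC_0`, `MCH_0`, `IRF_0`); in particular
  `k_RET = k_RBC (RBC_0/n_CTR) / (RET_0 (1 - IRF_0))`.
* A hemoglobin deficit drives an erythropoietin-like feedback
  `S = exp(γ (Hb_0 - Hb_tot)/Hb_0)` that stimulates precursor recruitment
  and accelerates marrow release of reticulocytes; two tolerance
  compartments (rate `k_TOL`) attenuate sustained stimulation, representing
  stem-cell reservoir depletion.
* Drug effect is an Imax model in steady-state exposure:
  `I = Imax · AUC_ss/(AUC_50 + AUC_ss)`, applied as a step over the
  treatment window to one of four pathways (mechanisms A–D: hemoglobin
  synthesis; precursor recruitment; precursor differentiation; hemoglobin
  synthesis with the feedback silenced).

The statistical layer puts log-normal inter-individual variability on the
baselines, the lifespan and `AUC_50` (`p_i = p · e^η`, `η ~ N(0, ω²)`), and
endpoint-specific additive/proportional/combined residual error on the
observations.

## Worked example

```python
import numpy as np
from erythrosim import (ModelParameters, MechanismSpec, derive_rates,
                        simulate_individual)

params = ModelParameters()          # typical male subject
rates = derive_rates(params)
print(f"k_RBC = {rates.k_RBC:.3f} /day, k_RET = {rates.k_RET:.4f} /day")

# 120 days of a hemoglobin-synthesis inhibitor at twice the half-maximal
# exposure (40 % pathway inhibition), then 120 days of follow-up
mech = MechanismSpec("A", AUC_ss=2 * params.AUC50)
df = simulate_individual(params, mech, grid=np.arange(0.0, 241.0))
end = df[df.time == 119].iloc[0]
print(f"day 119: MCH {end.MCH:.1f} pg, RET {end.RET:.1f} e9/L, "
      f"Hb_tot {end.Hb_tot:.1f} g/L")
```

prints

```
k_RBC = 0.032 /day, k_RET = 1.0357 /day
day 119: MCH 20.0 pg, RET 52.6 e9/L, Hb_tot 119.1 g/L
```

i.e. after 120 days of 40 % inhibition the mean corpuscular hemoglobin has
fallen from 29.8 toward its long-run floor `0.6 x 29.8 = 17.9` pg, total
hemoglobin has dropped ~19 %, and the feedback has raised circulating
reticulocytes from 39.8 to a new plateau of ~53 e9/L.  The same applies at
population scale:

```python
from erythrosim import PopulationModel, mechanism_panel
panel = mechanism_panel(PopulationModel(), mechanisms=("D",),
                        exposure_multiples=(2.0,), n=500, seed=11)
```

yields median and 90 % prediction-interval bands per endpoint; with the
feedback silenced (mechanism D) the lower hemoglobin band crosses the
100 g/L moderate-anemia threshold during treatment, which none of the
feedback-intact mechanisms do.

A full synthetic trial (62 subjects: placebo/10/30/60 mg for 120 days,
hematology at 20 visits over 34 weeks) with a truth sidecar for recovery
scoring:

```sh
erythrosim generate --seed 1 --out trial.csv
erythrosim fit --data trial.csv --out estimates.csv
erythrosim vpc --data trial.csv --n-rep 200 --seed 1 --out vpc.csv
```

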