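"""Structural model parameters and derived rate constants.

The erythropoiesis model is parameterized by cell lifespans, baseline blood
counts and the feedback / tolerance / drug-potency constants.  Everything the
ODE right-hand side needs beyond the raw parameters (transit rate constants,
the premature-release probability, the baseline cell flux and baseline
precursor pool) is computed once by :func:`derive_rates` from the steady-state
(homeostasis) conditions.

Units
-----
time            days
reticulocyte side   1e9 cells/L
erythrocyte side    1e12 cells/L
MCH             pg per cell
hemoglobin      g/L
exposure (AUC)  mg/L*h
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """A structural parameter is missing, non-positive or out of range."""


#: conversion between the reticulocyte (1e9/L) and erythrocyte (1e12/L) count
#: scales; also converts pg * 1e9 cells/L to g/L for the hemoglobin inflow.
UNIT_RET_TO_RBC = 1e-3


@dataclass(frozen=True)
class ModelParameters:
    """Typical (or individual) structural parameters.

    Defaults are the male typical estimates of the erythropoiesis model:
    precursor transit time fixed at 5 days, erythrocyte lifespan 125 days,
    baseline reticulocytes 39.8e9/L, baseline RBC 4.91e12/L, baseline MCH
    29.80 pg, baseline immature reticulocyte fraction 4.71 %, feedback
    exponent 2.42, tolerance rate constant 0.022 /day, maximal pathway
    inhibition 0.6 and half-maximal exposure 16.5 mg/L*h.

    Attributes
    ----------
    LS_PRE : float
        Precursor transit time in bone marrow, days (fixed at 5).
    LS_RBC : float
        Erythrocyte lifespan, days.
    RET_0 : float
        Baseline blood reticulocyte count, 1e9/L.
    RBC_0 : float
        Baseline erythrocyte count, 1e12/L (male typical by default).
    MCH_0 : float
        Baseline mean corpuscular hemoglobin, pg.
    IRF_0 : float
        Baseline immature reticulocyte fraction, in (0, 1).
    gamma_FB : float
        Feedback exponent on the fractional hemoglobin deficit.
    k_TOL : float
        Tolerance-compartment rate constant, 1/day.
    Imax : float
        Maximal fractional pathway inhibition, in [0, 1].
    AUC50 : float
        Exposure at half-maximal inhibition, mg/L*h.
    n_CTR : int
        Number of erythrocyte transit compartments (fixed at 4).
    """

    LS_PRE: float = 5.0
    LS_RBC: float = 125.0
    RET_0: float = 39.80
    RBC_0: float = 4.91
    MCH_0: float = 29.80
    IRF_0: float = 0.0471
    gamma_FB: float = 2.42
    k_TOL: float = 0.022
    Imax: float = 0.6
    AUC50: float = 16.50
    n_CTR: int = 4

    #: female baseline RBC offset (RBC_0,male - RBC_0,female) — of unclear
    #: scale in the source estimates; unused unless explicitly requested.
    RBC_diff_female: float = field(default=1.59, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("LS_PRE", "LS_RBC", "RET_0", "RBC_0", "MCH_0", "AUC50")
        for name in positive:
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if not (0.0 < self.IRF_0 < 1.0):
            raise ParameterError(f"IRF_0 must lie in (0, 1), got {self.IRF_0!r}")
        if not (0.0 <= self.Imax <= 1.0):
            raise ParameterError(f"Imax must lie in [0, 1], got {self.Imax!r}")
        if not (self.gamma_FB >= 0):
            raise ParameterError(f"gamma_FB must be >= 0, got {self.gamma_FB!r}")
        if not (self.k_TOL >= 0):
            raise ParameterError(f"k_TOL must be >= 0, got {self.k_TOL!r}")
        if int(self.n_CTR) != self.n_CTR or self.n_CTR < 1:
            raise ParameterError(f"n_CTR must be an integer >= 1, got {self.n_CTR!r}")

    def with_(self, **updates) -> "ModelParameters":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **updates)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DerivedRates:
    """Rate constants and baseline fluxes implied by homeostasis.

    k_PRE = 1/LS_PRE; k_RBC = n_CTR/LS_RBC; the reticulocyte maturation rate
    k_RET follows from flux balance at baseline,

        k_RET * RET_0 * (1 - IRF_0) = k_RBC * RBC_0 / n_CTR

    (right-hand side expressed on the 1e9/L scale), and the premature release
    probability p_release = IRF_0/(1 - IRF_0) reproduces the baseline IRF.
    """

    k_PRE: float
    k_RBC: float
    k_RET: float
    p_release: float
    F0: float      # baseline cell flux, 1e9 cells/L/day
    PRE_0: float   # baseline precursor pool, 1e9/L
    Hb_0: float    # baseline total hemoglobin, g/L
    LS_RET: float  # 1/k_RET, days


def derive_rates(params: ModelParameters) -> DerivedRates:
    """Compute all derived rate constants from the structural parameters.

    Parameters
    ----------
    params : ModelParameters
        Validated structural parameter set.

    Returns
    -------
    DerivedRates
        Rate constants, release probability and baseline fluxes.  The
        baseline cell flux ``F0`` (1e9 cells/L/day) balances the
        erythrocyte-side elimination ``k_RBC * RBC_0 / n_CTR`` exactly.
    """
    params.validate()
    k_PRE = 1.0 / params.LS_PRE
    k_RBC = params.n_CTR / params.LS_RBC
    # RBC_0 is carried on the 1e12/L scale; the flux balance is done on the
    # reticulocyte (1e9/L) scale.
    rbc0_e9 = params.RBC_0 / UNIT_RET_TO_RBC
    F0 = k_RBC * rbc0_e9 / params.n_CTR
    k_RET = F0 / (params.RET_0 * (1.0 - params.IRF_0))
    p_release = params.IRF_0 / (1.0 - params.IRF_0)
    PRE_0 = F0 * params.LS_PRE
    Hb_0 = params.RBC_0 * params.MCH_0
    return DerivedRates(
        k_PRE=k_PRE,
        k_RBC=k_RBC,
        k_RET=k_RET,
        p_release=p_release,
        F0=F0,
        PRE_0=PRE_0,
        Hb_0=Hb_0,
        LS_RET=1.0 / k_RET,
    )
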