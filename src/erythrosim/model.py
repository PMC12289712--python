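"""Structural erythropoiesis model: steady state, drug effect, feedback, RHS.

The system tracks bone-marrow precursors (PRE), two tolerance compartments
that lag the precursor pool, immature/mature reticulocytes in marrow and
blood, and two parallel four-compartment transit chains for circulating
erythrocytes and their hemoglobin.  Homeostasis fixes every initial condition
and rate constant from the observable baselines (RET_0, RBC_0, MCH_0, IRF_0)
and the lifespans; a drug perturbs the system through an Imax model driven by
steady-state exposure, on one of four pathways:

=========  ==================================================================
mechanism  pathway inhibited during the treatment window
=========  ==================================================================
A          hemoglobin synthesis (per-cell Hb content of newly formed cells)
B          precursor recruitment (R_in)
C          precursor-to-reticulocyte differentiation (k_PRE)
D          hemoglobin synthesis + full silencing of the Hb-driven feedback
=========  ==================================================================

A fractional hemoglobin deficit stimulates both precursor recruitment and
the reticulocyte bone-marrow exit rates (earlier and faster release into
the circulation) through a shared exponential feedback term, mimicking the
endogenous erythropoietin response; the tolerance compartments attenuate
sustained stimulation, representing depletion of the stem-cell reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np

from . import _kernel
from ._kernel import (  # noqa: F401  (re-exported state layout)
    N_STATES, STATE_NAMES, IDX_PRE, IDX_TOL1, IDX_TOL2,
    IDX_RET_IMM_BM, IDX_RET_IMM_BL, IDX_RET_MAT_BM, IDX_RET_MAT_BL,
    IDX_RBC, IDX_HB, IntegrationError,
)
from .params import ModelParameters, DerivedRates, derive_rates, ParameterError

logger = logging.getLogger(__name__)

MECHANISMS = ("none", "A", "B", "C", "D")


class DegenerateStateError(ValueError):
    """Observation requested from a state with zero cells."""


@dataclass(frozen=True)
class MechanismSpec:
    """A hypothetical drug-target interaction and its exposure.

    Attributes
    ----------
    mechanism : {"none", "A", "B", "C", "D"}
        Pathway inhibited (see module docstring).
    AUC_ss : float
        Steady-state exposure, mg/L*h; enters the Imax model directly
        (exposure is a step over the treatment window; no washout kinetics).
    t_on, t_off : float
        Treatment window in days, inhibition active on ``[t_on, t_off)``.
    """

    mechanism: str = "none"
    AUC_ss: float = 0.0
    t_on: float = 0.0
    t_off: float = 120.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.AUC_ss < 0:
            raise ValueError(f"AUC_ss must be >= 0, got {self.AUC_ss!r}")
        if not (self.t_on < self.t_off):
            raise ValueError("t_on must be strictly less than t_off")


PLACEBO = MechanismSpec("none", 0.0)


@dataclass(frozen=True)
class ModelOutputs:
    """Observable endpoints computed from a model state (scalars or arrays)."""

    RET: object    # blood reticulocytes, 1e9/L
    RBC: object    # erythrocytes, 1e12/L
    MCH: object    # mean corpuscular hemoglobin, pg
    IRF: object    # immature reticulocyte fraction
    Hb_tot: object  # total hemoglobin, g/L

    def as_dict(self) -> dict:
        return {"RET": self.RET, "RBC": self.RBC, "MCH": self.MCH,
                "IRF": self.IRF, "Hb_tot": self.Hb_tot}


ENDPOINTS = ("RET", "RBC", "MCH", "IRF", "Hb_tot")


def inhibition(AUC_ss: float, Imax: float, AUC50: float,
               t: float | None = None, t_on: float = 0.0,
               t_off: float = 120.0) -> float:
    """Fractional pathway inhibition under the Imax exposure-response model.

    Returns ``Imax * AUC_ss / (AUC50 + AUC_ss)`` while treatment is active
    (``t_on <= t < t_off``, or always if ``t`` is None), else 0.  At an
    exposure of half AUC50 with Imax 0.6 this is 20 % inhibition; at twice
    AUC50 it is 40 %.
    """
    if AUC_ss < 0:
        raise ParameterError(f"AUC_ss must be >= 0, got {AUC_ss!r}")
    if AUC50 <= 0:
        raise ParameterError(f"AUC50 must be > 0, got {AUC50!r}")
    if not (0.0 <= Imax <= 1.0):
        raise ParameterError(f"Imax must lie in [0, 1], got {Imax!r}")
    if t is not None and not (t_on <= t < t_off):
        return 0.0
    return Imax * AUC_ss / (AUC50 + AUC_ss)


def stimulation(Hb_tot: float, Hb_0: float, gamma_FB: float,
                feedback_disabled: bool = False,
                deficit_stimulates: bool = True) -> float:
    """Exponential feedback factor on recruitment and reticulocyte release.

    ``exp(gamma_FB * (Hb_0 - Hb_tot)/Hb_0)``: a hemoglobin deficit stimulates
    (factor > 1), an excess suppresses.  With ``deficit_stimulates=False``
    the sign of the fractional change is flipped.  Returns 1 when the
    feedback is disabled (mechanism D during treatment) or ``gamma_FB == 0``.
    """
    if Hb_0 <= 0:
        raise ParameterError(f"Hb_0 must be > 0, got {Hb_0!r}")
    if feedback_disabled or gamma_FB == 0:
        return 1.0
    sign = 1.0 if deficit_stimulates else -1.0
    return math.exp(sign * gamma_FB * (Hb_0 - Hb_tot) / Hb_0)


def tolerance_modulation(TOL2: float, PRE_0: float,
                         floor: float | None = None) -> float:
    """Delayed inverse-proportional modulation of precursor recruitment.

    Returns ``PRE_0 / TOL2``: 1 at baseline, < 1 once the delayed precursor
    signal exceeds baseline (attenuating sustained stimulation).  ``TOL2``
    below the floor (default ``1e-9 * PRE_0``) is clamped with a warning —
    this signals numerically degenerate depletion, not a physiological state.
    """
    if PRE_0 <= 0:
        raise ParameterError(f"PRE_0 must be > 0, got {PRE_0!r}")
    if floor is None:
        floor = 1e-9 * PRE_0
    if TOL2 <= floor:
        logger.warning("tolerance state TOL2=%g clamped to floor %g "
                       "(degenerate depletion)", TOL2, floor)
        TOL2 = floor
    return PRE_0 / TOL2


def steady_state(params: ModelParameters, hb_mode: str = "mass") -> np.ndarray:
    """Drug-free equilibrium state vector (length 15).

    All pools are set so that every derivative vanishes and the observed
    endpoints reproduce RET_0, RBC_0, MCH_0, IRF_0 and Hb_0 exactly.
    """
    arrs = _kernel.PopulationArrays([params])
    return _kernel.steady_state_matrix(arrs, hb_mode=hb_mode)[0]


def rhs(t: float, state: np.ndarray, params: ModelParameters,
        rates: DerivedRates | None = None,
        mech: MechanismSpec = PLACEBO, *, hb_mode: str = "mass",
        deficit_stimulates: bool = True,
        ret_feedback: str = "release") -> np.ndarray:
    """Time derivative of the 15-state system for a single individual.

    This is the reference (single-subject) entry point to the same kernel the
    population integrator uses.  ``rates`` is accepted for interface
    symmetry; when omitted it is derived from ``params``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise IntegrationError("non-finite state passed to rhs")
    if np.any(state < 0):
        raise IntegrationError("negative state passed to rhs")
    arrs = _kernel.PopulationArrays([params])
    mech_code = _kernel.MECH_CODES[mech.mechanism]
    active = mech.t_on <= t < mech.t_off
    aucs = np.array([mech.AUC_ss], dtype=float)
    eMCH, eRin, ekPRE, gamma_eff = _kernel._segment_multipliers(
        arrs, mech_code, active, aucs, deficit_stimulates)
    content = 1 if hb_mode == "content" else 0
    fb_uniform = 1 if ret_feedback == "uniform" else 0
    return _kernel._rhs_core(
        t, state.copy(), 1, arrs.kPRE, arrs.kRBC, arrs.kRET, arrs.p_rel,
        arrs.F0, arrs.PRE0, arrs.Hb0, arrs.MCH0, arrs.kTOL,
        gamma_eff, eMCH, eRin, ekPRE, content, fb_uniform)


def observe(state: np.ndarray, hb_mode: str = "mass") -> ModelOutputs:
    """Map model state(s) to the observable endpoints.

    Accepts a single state vector or any array whose last axis holds the 15
    states (e.g. the ``(n, T, 15)`` output of the population integrator).
    Blood reticulocytes are the sum of the immature and mature blood pools;
    RBC and total hemoglobin are summed over the four transit compartments;
    MCH is total hemoglobin over total cell count.  Reticulocytes (1-2 % of
    circulating cells) carry no modeled hemoglobin.
    """
    y = np.asarray(state, dtype=float)
    if y.shape[-1] != N_STATES:
        raise ValueError(f"last axis must have length {N_STATES}, got {y.shape}")
    ret = y[..., IDX_RET_IMM_BL] + y[..., IDX_RET_MAT_BL]
    rbc = y[..., IDX_RBC].sum(axis=-1)
    if np.any(ret <= 0) or np.any(rbc <= 0):
        raise DegenerateStateError(
            "observe() requires positive blood reticulocyte and RBC pools")
    if hb_mode == "content":
        hb_tot = (y[..., IDX_RBC] * y[..., IDX_HB]).sum(axis=-1)
    else:
        hb_tot = y[..., IDX_HB].sum(axis=-1)
    mch = hb_tot / rbc
    irf = y[..., IDX_RET_IMM_BL] / ret
    if y.ndim == 1:
        return ModelOutputs(float(ret), float(rbc), float(mch), float(irf),
                            float(hb_tot))
    return ModelOutputs(ret, rbc, mch, irf, hb_tot)
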