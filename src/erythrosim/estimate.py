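"""Likelihood-based fitting of the erythropoiesis model to observation tables.

Estimation is deliberately desk-scale: a naive-pooled maximum-likelihood fit
(one typical parameter vector for all subjects, individual exposures taken
from the data) and a classical two-stage fit (independent per-subject fits,
then geometric mean and log-scale spread as typical value and %CV).  Both
are exposed as scikit-learn-style estimators (``fit``, fitted attributes
with a trailing underscore, ``get_params``/``set_params``) so they compose
with sklearn model-selection tooling; :func:`fit_pooled` and
:func:`fit_two_stage` are thin functional wrappers.

The observation likelihood is Gaussian with the endpoint-specific combined
error variance ``sigma^2 = sd_add^2 + pred^2 * sd_prop^2``.  Total
hemoglobin records (DVID 5) are excluded from fitting by default and
reserved for external validation.

Free parameters are optimized on transformed scales (log for positive
parameters, logit for fractions) with bound constraints, by Nelder-Mead
with restarts; multi-start with seeded jitter guards against local minima.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _kernel
from .io import DVID_TO_ENDPOINT, validate_table
from .model import observe
from .params import ModelParameters, ParameterError
from .population import DEFAULT_RESIDUAL, ResidualSpec

logger = logging.getLogger(__name__)

_PENALTY = 1e10

#: default free parameters of the pooled fit (LS_PRE and Imax stay fixed)
DEFAULT_FREE = ("LS_RBC", "RET_0", "RBC_0", "MCH_0", "IRF_0", "gamma_FB",
                "AUC50", "sd_RET_prop", "sd_RBC_add", "sd_MCH_add",
                "sd_IRF_add", "sd_IRF_prop")

#: natural-scale box bounds per parameter
DEFAULT_BOUNDS = {
    "LS_PRE": (1.0, 20.0),
    "LS_RBC": (30.0, 300.0),
    "RET_0": (5.0, 200.0),
    "RBC_0": (2.0, 8.0),
    "MCH_0": (15.0, 45.0),
    "IRF_0": (1e-3, 0.5),
    "gamma_FB": (0.05, 20.0),
    "k_TOL": (1e-4, 1.0),
    "Imax": (0.01, 0.99),
    "AUC50": (0.5, 500.0),
}
_SD_BOUNDS = (1e-6, 1e3)

DEFAULT_TRANSFORMS = {"IRF_0": "logit", "Imax": "logit"}  # others: log


def _fwd(value, transform):
    if transform == "log":
        return math.log(value)
    if transform == "logit":
        return math.log(value / (1.0 - value))
    return value


def _inv(z, transform):
    if transform == "log":
        return math.exp(z)
    if transform == "logit":
        return 1.0 / (1.0 + math.exp(-z))
    return z


def _is_sd_name(name: str) -> bool:
    return name.startswith("sd_")


def _split_sd_name(name: str):
    # "sd_RET_prop" -> ("RET", "prop"); "sd_Hb_tot_add" -> ("Hb_tot", "add")
    body = name[3:]
    endpoint, _, comp = body.rpartition("_")
    if comp not in ("add", "prop") or endpoint not in (
            "RET", "RBC", "MCH", "IRF", "Hb_tot"):
        raise ParameterError(f"unrecognized residual parameter name {name!r}")
    return endpoint, comp


@dataclass(frozen=True)
class FitSpec:
    """Declarative description of a fit: free set, bounds, start, options."""

    free: tuple = DEFAULT_FREE
    fixed: dict = field(default_factory=dict)   # overrides on ModelParameters
    bounds: dict = field(default_factory=dict)
    start: dict = field(default_factory=dict)
    transforms: dict = field(default_factory=dict)
    n_starts: int = 5
    jitter_sd: float = 0.2
    seed: int = 0
    maxfev: int | None = None
    mechanism: str = "A"


@dataclass
class FitResult:
    """Estimates on the natural scale plus fit diagnostics."""

    estimates: dict
    neg2loglik: float
    converged: bool
    n_evals: int
    params: ModelParameters
    residual: dict
    per_subject: pd.DataFrame | None = None
    iiv_cv: dict | None = None
    se: dict | None = None
    condition_number: float | None = None


class _RecordIndex:
    """Pre-digested observation table for fast repeated likelihood evals."""

    def __init__(self, data: pd.DataFrame, endpoints):
        validate_table(data)
        d = data[data["DVID"].isin([k for k, v in DVID_TO_ENDPOINT.items()
                                    if v in endpoints])]
        d = d.dropna(subset=["DV"])
        if d.empty:
            raise ValueError("no usable observation records for the fit")
        self.subjects = np.array(sorted(d["ID"].unique()))
        subj_pos = {s: i for i, s in enumerate(self.subjects)}
        self.n = self.subjects.size
        first = d.groupby("ID").first()
        self.aucs = first.loc[self.subjects, "AUC"].to_numpy(dtype=float)
        self.grid = np.array(sorted(d["TIME"].unique()), dtype=float)
        time_pos = {t: i for i, t in enumerate(self.grid)}
        self.records = {}
        for endpoint in endpoints:
            sub = d[d["DVID"] == {v: k for k, v in DVID_TO_ENDPOINT.items()}[endpoint]]
            if sub.empty:
                continue
            self.records[endpoint] = (
                sub["ID"].map(subj_pos).to_numpy(dtype=int),
                sub["TIME"].map(time_pos).to_numpy(dtype=int),
                sub["DV"].to_numpy(dtype=float),
            )

    def n_records(self) -> int:
        return sum(v[2].size for v in self.records.values())


def _predict_outputs(idx: _RecordIndex, params: ModelParameters, *,
                     mechanism: str, t_on: float, t_off: float, rtol: float,
                     hb_mode: str, deficit_stimulates: bool,
                     ret_feedback: str = "release") -> dict:
    traj = _kernel.integrate_population(
        [params] * idx.n, idx.aucs, mechanism, idx.grid,
        t_on=t_on, t_off=t_off, rtol=rtol, hb_mode=hb_mode,
        deficit_stimulates=deficit_stimulates, ret_feedback=ret_feedback)
    return observe(traj, hb_mode=hb_mode).as_dict()


def _nll(idx: _RecordIndex, params: ModelParameters, residual: dict, *,
         mechanism: str, t_on: float, t_off: float, rtol: float,
         hb_mode: str, deficit_stimulates: bool,
         ret_feedback: str = "release") -> float:
    outputs = _predict_outputs(idx, params, mechanism=mechanism, t_on=t_on,
                               t_off=t_off, rtol=rtol, hb_mode=hb_mode,
                               deficit_stimulates=deficit_stimulates,
                               ret_feedback=ret_feedback)
    total = 0.0
    for endpoint, (si, ti, obs) in idx.records.items():
        pred = outputs[endpoint][si, ti]
        var = residual[endpoint].variance(pred)
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            raise FloatingPointError(
                f"non-positive residual variance for endpoint {endpoint}")
        res = obs - pred
        total += 0.5 * float(np.sum(np.log(2.0 * np.pi * var) + res * res / var))
    return total


def negloglik(params: ModelParameters, data: pd.DataFrame,
              residual: dict | None = None, *, mechanism: str = "A",
              t_on: float = 0.0, t_off: float = 120.0, rtol: float = 1e-6,
              hb_mode: str = "mass", deficit_stimulates: bool = True,
              ret_feedback: str = "release",
              endpoints=("RET", "RBC", "MCH", "IRF")) -> float:
    """Negative Gaussian log-likelihood of an observation table.

    Deterministic given its inputs; -2 times this value is the objective
    function value reported by the fitters.  Integration failures return a
    large penalized value (optimizer-safe) with a logged warning.
    """
    residual = dict(DEFAULT_RESIDUAL) if residual is None else residual
    idx = _RecordIndex(data, endpoints)
    try:
        return _nll(idx, params, residual, mechanism=mechanism, t_on=t_on,
                    t_off=t_off, rtol=rtol, hb_mode=hb_mode,
                    deficit_stimulates=deficit_stimulates,
                    ret_feedback=ret_feedback)
    except (_kernel.IntegrationError, FloatingPointError) as exc:
        logger.warning("likelihood evaluation penalized: %s", exc)
        return _PENALTY


def default_start_from_data(data: pd.DataFrame) -> dict:
    """Data-driven starting values: baseline means for the baselines, a
    literature-style erythrocyte lifespan, unit feedback and the median
    active exposure as the potency start."""
    d = data.dropna(subset=["DV"])
    t0 = d["TIME"].min()
    base = d[d["TIME"] == t0]
    start = {"LS_RBC": 120.0, "gamma_FB": 1.0, "k_TOL": 0.02}
    for endpoint, name in (("RET", "RET_0"), ("RBC", "RBC_0"),
                           ("MCH", "MCH_0"), ("IRF", "IRF_0")):
        code = {"RET": 1, "RBC": 2, "MCH": 3, "IRF": 4}[endpoint]
        vals = base.loc[base["DVID"] == code, "DV"]
        if len(vals):
            start[name] = float(vals.mean())
    active = d.loc[d["AUC"] > 0, "AUC"]
    start["AUC50"] = float(active.median()) if len(active) else 10.0
    return start


class PooledMLEstimator(BaseEstimator):
    """Naive-pooled maximum-likelihood fit of the typical parameters.

    All subjects share one structural parameter vector; individual
    exposures are read from the table's AUC column.  Residual SDs named in
    ``free`` (e.g. ``"sd_RET_prop"``) are estimated jointly with the
    structural parameters.

    Parameters
    ----------
    free : tuple of str
        Names of the free parameters (ModelParameters fields and/or
        ``sd_<endpoint>_<add|prop>`` residual SDs).
    base_params : ModelParameters or None
        Values for the fixed parameters (default: the typical male set,
        i.e. LS_PRE = 5 and Imax = 0.6 stay fixed).
    residual : dict or None
        Endpoint -> ResidualSpec; starting values for free SDs, fixed
        values otherwise.
    start : dict or None
        Starting values for free structural parameters; anything missing
        is filled from the data (baseline means, median exposure) via
        :func:`default_start_from_data`, then from ``base_params``.
    n_starts : int
        Multi-start count; the first start is unjittered, the rest are
        log-normally jittered in transformed space (seeded).
    mechanism : str
        Drug mechanism assumed when predicting active subjects.
    endpoints : tuple
        Endpoints entering the likelihood (Hb_tot excluded by default).

    Attributes
    ----------
    params_ : ModelParameters
        Fitted structural parameters (free + fixed).
    residual_ : dict
        Endpoint -> ResidualSpec with fitted SDs.
    estimates_ : dict
        Free-parameter estimates on the natural scale.
    neg2loglik_ : float
        -2 log-likelihood at the optimum.
    converged_ : bool
    n_evals_ : int
    se_, condition_number_, singular_info_ :
        Asymptotic SEs (natural scale), condition number of the observed
        information and a near-singularity flag; only when
        ``compute_se=True``.
    """

    def __init__(self, free=DEFAULT_FREE, base_params=None, residual=None,
                 start=None, bounds=None, transforms=None, n_starts=5,
                 jitter_sd=0.2, seed=0, maxfev=None, xatol=1e-4, fatol=1e-5,
                 max_restarts=2, mechanism="A", t_on=0.0, t_off=120.0,
                 endpoints=("RET", "RBC", "MCH", "IRF"), rtol=1e-6,
                 hb_mode="mass", deficit_stimulates=True,
                 ret_feedback="release", compute_se=False):
        self.free = free
        self.base_params = base_params
        self.residual = residual
        self.start = start
        self.bounds = bounds
        self.transforms = transforms
        self.n_starts = n_starts
        self.jitter_sd = jitter_sd
        self.seed = seed
        self.maxfev = maxfev
        self.xatol = xatol
        self.fatol = fatol
        self.max_restarts = max_restarts
        self.mechanism = mechanism
        self.t_on = t_on
        self.t_off = t_off
        self.endpoints = endpoints
        self.rtol = rtol
        self.hb_mode = hb_mode
        self.deficit_stimulates = deficit_stimulates
        self.ret_feedback = ret_feedback
        self.compute_se = compute_se

    # -- plumbing ----------------------------------------------------------

    def _setup(self, data):
        base = self.base_params if self.base_params is not None else ModelParameters()
        residual = {k: v for k, v in DEFAULT_RESIDUAL.items()}
        if self.residual is not None:
            residual.update(self.residual)
        free = tuple(self.free)
        for name in free:
            if not _is_sd_name(name) and not hasattr(base, name):
                raise ParameterError(f"unknown free parameter {name!r}")
        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)
        transforms = dict(DEFAULT_TRANSFORMS)
        if self.transforms:
            transforms.update(self.transforms)

        data_start = default_start_from_data(data)
        start = {}
        for name in free:
            if self.start and name in self.start:
                start[name] = self.start[name]
            elif _is_sd_name(name):
                endpoint, comp = _split_sd_name(name)
                spec = residual[endpoint]
                v = spec.sd_add if comp == "add" else spec.sd_prop
                start[name] = v if v > 0 else 0.1
            elif name in data_start:
                start[name] = data_start[name]
            else:
                start[name] = getattr(base, name)
        return base, residual, free, bounds, transforms, start

    def _vector_to_params(self, z, free, transforms, base, residual):
        updates, sds = {}, {}
        for name, zi in zip(free, z):
            tr = transforms.get(name, "log")
            value = _inv(zi, tr)
            if _is_sd_name(name):
                sds[name] = value
            else:
                updates[name] = value
        params = base.with_(**updates)
        res = dict(residual)
        for name, value in sds.items():
            endpoint, comp = _split_sd_name(name)
            spec = res[endpoint]
            res[endpoint] = ResidualSpec(
                spec.kind,
                sd_add=value if comp == "add" else spec.sd_add,
                sd_prop=value if comp == "prop" else spec.sd_prop)
        return params, res

    def _objective(self, idx, free, transforms, base, residual):
        n_evals = [0]

        def fun(z):
            n_evals[0] += 1
            try:
                params, res = self._vector_to_params(z, free, transforms,
                                                     base, residual)
                return _nll(idx, params, res, mechanism=self.mechanism,
                            t_on=self.t_on, t_off=self.t_off, rtol=self.rtol,
                            hb_mode=self.hb_mode,
                            deficit_stimulates=self.deficit_stimulates,
                            ret_feedback=self.ret_feedback)
            except (_kernel.IntegrationError, ParameterError,
                    FloatingPointError, OverflowError) as exc:
                logger.warning("objective penalized at %s: %s", z, exc)
                return _PENALTY

        return fun, n_evals

    # -- API ---------------------------------------------------------------

    def fit(self, data, y=None):
        """Fit to an observation table (long-format DataFrame)."""
        data = pd.DataFrame(data)
        base, residual, free, bounds, transforms, start = self._setup(data)
        idx = _RecordIndex(data, self.endpoints)
        z0 = np.array([_fwd(start[name], transforms.get(name, "log"))
                       for name in free])
        zbounds = []
        for name in free:
            lo, hi = bounds.get(name, _SD_BOUNDS if _is_sd_name(name)
                                else (1e-8, 1e8))
            tr = transforms.get(name, "log")
            zbounds.append((_fwd(lo, tr), _fwd(hi, tr)))
        fun, n_evals = self._objective(idx, free, transforms, base, residual)
        maxfev = self.maxfev if self.maxfev else 300 * len(free)

        rng = np.random.default_rng(self.seed)
        best = None
        self.starts_ = []
        for s in range(max(1, self.n_starts)):
            z_init = z0 if s == 0 else z0 + rng.normal(0, self.jitter_sd,
                                                       size=z0.size)
            z_init = np.clip(z_init, [b[0] for b in zbounds],
                             [b[1] for b in zbounds])
            res = None
            for _restart in range(1 + self.max_restarts):
                prev = res.fun if res is not None else np.inf
                res = minimize(fun, z_init, method="Nelder-Mead",
                               bounds=zbounds,
                               options={"maxfev": maxfev, "xatol": self.xatol,
                                        "fatol": self.fatol, "adaptive": True})
                z_init = res.x
                if prev - res.fun < max(10 * self.fatol, 1e-8):
                    break
            self.starts_.append((float(res.fun), res.x.copy(), bool(res.success)))
            if best is None or res.fun < best.fun:
                best = res
        if best.fun >= _PENALTY:
            raise RuntimeError(
                "all optimization starts failed; per-start objectives: "
                + ", ".join(f"{f:.6g}" for f, _z, _s in self.starts_))

        self.params_, self.residual_ = self._vector_to_params(
            best.x, free, transforms, base, residual)
        self.free_ = free
        self.transforms_ = transforms
        # estimates that land on (or hug) a box bound signal a flat
        # likelihood direction; downstream aggregation treats them as
        # non-identified
        self.at_bounds_ = [
            name for name, zi, (lo, hi) in zip(free, best.x, zbounds)
            if min(zi - lo, hi - zi) < 0.15]
        self.estimates_ = {}
        for name, zi in zip(free, best.x):
            self.estimates_[name] = _inv(zi, transforms.get(name, "log"))
        self.neg2loglik_ = 2.0 * float(best.fun)
        self.converged_ = bool(best.success)
        self.n_evals_ = int(n_evals[0])
        self._idx = idx
        self._fun = fun
        self._z_opt = best.x.copy()
        if self.compute_se:
            self._compute_information(best.x, fun, free, transforms)
        return self

    def _compute_information(self, z, fun, free, transforms, eps=1e-3):
        """Observed information (Hessian of the NLL) by central differences
        in transformed space; flags near-singular (practically
        non-identifiable) fits."""
        p = z.size
        H = np.empty((p, p))
        f0 = fun(z)
        for i in range(p):
            for j in range(i, p):
                zi = z.copy()
                if i == j:
                    zi[i] = z[i] + eps
                    fp = fun(zi)
                    zi[i] = z[i] - eps
                    fm = fun(zi)
                    H[i, i] = (fp - 2 * f0 + fm) / eps ** 2
                else:
                    zpp = z.copy(); zpp[[i, j]] += eps
                    zpm = z.copy(); zpm[i] += eps; zpm[j] -= eps
                    zmp = z.copy(); zmp[i] -= eps; zmp[j] += eps
                    zmm = z.copy(); zmm[[i, j]] -= eps
                    H[i, j] = H[j, i] = (
                        fun(zpp) - fun(zpm) - fun(zmp) + fun(zmm)) / (4 * eps ** 2)
        self.information_ = H
        eig = np.linalg.eigvalsh(H)
        self.condition_number_ = float(abs(eig[-1]) / max(abs(eig[0]), 1e-300)) \
            if eig[0] != 0 else np.inf
        self.singular_info_ = bool(eig[0] <= 0 or self.condition_number_ > 1e8)
        if self.singular_info_:
            logger.warning("observed information is near-singular "
                           "(condition number %.3g): the free set is "
                           "practically non-identifiable", self.condition_number_)
            self.se_ = {name: np.nan for name in free}
            return
        cov = np.linalg.inv(H)
        self.se_ = {}
        for i, name in enumerate(free):
            tr = transforms.get(name, "log")
            sd_z = math.sqrt(max(cov[i, i], 0.0))
            est = self.estimates_[name]
            if tr == "log":
                self.se_[name] = est * sd_z          # delta method
            elif tr == "logit":
                self.se_[name] = est * (1 - est) * sd_z
            else:
                self.se_[name] = sd_z

    def predict(self, data) -> pd.DataFrame:
        """Typical-subject predictions for every fitted-endpoint record."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        idx = _RecordIndex(pd.DataFrame(data), self.endpoints)
        outputs = _predict_outputs(
            idx, self.params_, mechanism=self.mechanism, t_on=self.t_on,
            t_off=self.t_off, rtol=self.rtol, hb_mode=self.hb_mode,
            deficit_stimulates=self.deficit_stimulates,
            ret_feedback=self.ret_feedback)
        rows = []
        for endpoint, (si, ti, obs) in idx.records.items():
            pred = outputs[endpoint][si, ti]
            rows.append(pd.DataFrame({
                "ID": idx.subjects[si], "TIME": idx.grid[ti],
                "endpoint": endpoint, "DV": obs, "PRED": pred}))
        return pd.concat(rows, ignore_index=True)

    def score(self, data, y=None) -> float:
        """Mean log-likelihood per record (higher is better)."""
        idx = _RecordIndex(pd.DataFrame(data), self.endpoints)
        nll = _nll(idx, self.params_, self.residual_, mechanism=self.mechanism,
                   t_on=self.t_on, t_off=self.t_off, rtol=self.rtol,
                   hb_mode=self.hb_mode,
                   deficit_stimulates=self.deficit_stimulates,
                   ret_feedback=self.ret_feedback)
        return -nll / idx.n_records()


class TwoStageEstimator(BaseEstimator):
    """Classical two-stage fit: independent per-subject ML fits, then
    geometric mean (typical value) and log-scale SD -> %CV (IIV) per
    parameter.

    Subjects whose fit fails to converge (or errors) are excluded from the
    aggregation and listed in ``failed_subjects_``; the fit errors out if
    more than ``max_fail_frac`` of subjects fail.
    """

    def __init__(self, free=("RET_0", "RBC_0", "MCH_0"), base_params=None,
                 residual=None, start=None, bounds=None, transforms=None,
                 n_starts=1, jitter_sd=0.2, seed=0, maxfev=None, xatol=1e-4,
                 fatol=1e-5, max_restarts=1, mechanism="A", t_on=0.0,
                 t_off=120.0, endpoints=("RET", "RBC", "MCH", "IRF"),
                 rtol=1e-6, hb_mode="mass", deficit_stimulates=True,
                 ret_feedback="release", max_fail_frac=0.2):
        self.free = free
        self.base_params = base_params
        self.residual = residual
        self.start = start
        self.bounds = bounds
        self.transforms = transforms
        self.n_starts = n_starts
        self.jitter_sd = jitter_sd
        self.seed = seed
        self.maxfev = maxfev
        self.xatol = xatol
        self.fatol = fatol
        self.max_restarts = max_restarts
        self.mechanism = mechanism
        self.t_on = t_on
        self.t_off = t_off
        self.endpoints = endpoints
        self.rtol = rtol
        self.hb_mode = hb_mode
        self.deficit_stimulates = deficit_stimulates
        self.ret_feedback = ret_feedback
        self.max_fail_frac = max_fail_frac

    def fit(self, data, y=None):
        data = pd.DataFrame(data)
        validate_table(data)
        subjects = sorted(data["ID"].unique())
        rows, failed, boundary, total_n2ll = [], [], [], 0.0
        for sid in subjects:
            sub = data[data["ID"] == sid]
            est = PooledMLEstimator(
                free=self.free, base_params=self.base_params,
                residual=self.residual, start=self.start, bounds=self.bounds,
                transforms=self.transforms, n_starts=self.n_starts,
                jitter_sd=self.jitter_sd, seed=self.seed, maxfev=self.maxfev,
                xatol=self.xatol, fatol=self.fatol,
                max_restarts=self.max_restarts, mechanism=self.mechanism,
                t_on=self.t_on, t_off=self.t_off, endpoints=self.endpoints,
                rtol=self.rtol, hb_mode=self.hb_mode,
                deficit_stimulates=self.deficit_stimulates,
                ret_feedback=self.ret_feedback)
            try:
                est.fit(sub)
            except Exception as exc:
                logger.warning("subject %s excluded from two-stage fit: %s",
                               sid, exc)
                failed.append(sid)
                continue
            if not est.converged_:
                logger.warning("subject %s did not converge; excluded", sid)
                failed.append(sid)
                continue
            if est.at_bounds_:
                logger.warning("subject %s estimate at bound for %s "
                               "(flat likelihood); excluded", sid,
                               est.at_bounds_)
                boundary.append(sid)
                continue
            rows.append({"ID": sid, **est.estimates_})
            total_n2ll += est.neg2loglik_
        if len(failed) > self.max_fail_frac * len(subjects):
            raise RuntimeError(
                f"two-stage fit failed for {len(failed)}/{len(subjects)} "
                f"subjects: {failed}")
        if len(rows) < 2:
            raise RuntimeError(
                "two-stage fit left fewer than two usable subjects "
                f"({len(failed)} failed, {len(boundary)} at bounds)")
        per_subject = pd.DataFrame(rows)
        self.per_subject_ = per_subject
        self.failed_subjects_ = failed
        self.boundary_subjects_ = boundary
        self.typical_ = {}
        self.iiv_cv_ = {}
        for name in self.free:
            vals = per_subject[name].to_numpy(dtype=float)
            logs = np.log(vals)
            self.typical_[name] = float(np.exp(logs.mean()))
            sd = float(logs.std(ddof=1)) if vals.size > 1 else 0.0
            self.iiv_cv_[name] = 100.0 * math.sqrt(math.expm1(sd ** 2))
        base = self.base_params if self.base_params is not None else ModelParameters()
        struct = {k: v for k, v in self.typical_.items()
                  if not _is_sd_name(k)}
        self.params_ = base.with_(**struct)
        self.neg2loglik_ = float(total_n2ll)
        self.converged_ = True
        return self


# -- functional wrappers ----------------------------------------------------

def fit_pooled(data: pd.DataFrame, spec: FitSpec | None = None,
               **overrides) -> FitResult:
    """Pooled maximum-likelihood fit described by a :class:`FitSpec`."""
    spec = spec or FitSpec()
    base = ModelParameters().with_(**spec.fixed) if spec.fixed else None
    est = PooledMLEstimator(
        free=spec.free, base_params=base, start=spec.start or None,
        bounds=spec.bounds or None, transforms=spec.transforms or None,
        n_starts=spec.n_starts, jitter_sd=spec.jitter_sd, seed=spec.seed,
        maxfev=spec.maxfev, mechanism=spec.mechanism, **overrides)
    est.fit(data)
    result = FitResult(
        estimates=dict(est.estimates_), neg2loglik=est.neg2loglik_,
        converged=est.converged_, n_evals=est.n_evals_, params=est.params_,
        residual=dict(est.residual_))
    if getattr(est, "se_", None) is not None:
        result.se = dict(est.se_)
        result.condition_number = est.condition_number_
    return result


def fit_two_stage(data: pd.DataFrame, spec: FitSpec | None = None,
                  **overrides) -> FitResult:
    """Two-stage fit: per-subject estimates, geometric-mean typicals, %CVs."""
    spec = spec or FitSpec(free=("RET_0", "RBC_0", "MCH_0"))
    base = ModelParameters().with_(**spec.fixed) if spec.fixed else None
    est = TwoStageEstimator(
        free=spec.free, base_params=base, start=spec.start or None,
        bounds=spec.bounds or None, transforms=spec.transforms or None,
        n_starts=spec.n_starts, jitter_sd=spec.jitter_sd, seed=spec.seed,
        maxfev=spec.maxfev, mechanism=spec.mechanism, **overrides)
    est.fit(data)
    return FitResult(
        estimates=dict(est.typical_), neg2loglik=est.neg2loglik_,
        converged=est.converged_, n_evals=0, params=est.params_,
        residual=dict(est.residual or DEFAULT_RESIDUAL),
        per_subject=est.per_subject_, iiv_cv=dict(est.iiv_cv_))
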