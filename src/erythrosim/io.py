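"""Observation-table CSV dialect and structured configuration.

Observation tables use a NONMEM-style long format, one row per observation:

===== =========================================================
ID    subject identifier (integer)
TIME  days since first dose, >= 0
DVID  endpoint code: 1 RET, 2 RBC, 3 MCH, 4 IRF, 5 Hb_tot
DV    observed value in the endpoint's unit (empty = missing)
DOSE  daily dose, mg
AUC   individual steady-state exposure, mg/L*h
SEX   M or F
ARM   arm label
===== =========================================================

Units are fixed per DVID: RET 1e9/L, RBC 1e12/L, MCH pg, IRF fraction,
Hb_tot g/L.  Time in files is always days; IRF is stored as a fraction and
displayed as a percentage only in reports.

The configuration file is YAML with top-level sections ``parameters``,
``iiv_cv``, ``residual``, ``design`` and ``options``; parameter keys mirror
the published symbol names (``Feedback``, ``AUC_50``, ``RBC_0_male``, ...).
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ModelParameters
from .population import PopulationModel, ResidualSpec

ENDPOINT_TO_DVID = {"RET": 1, "RBC": 2, "MCH": 3, "IRF": 4, "Hb_tot": 5}
DVID_TO_ENDPOINT = {v: k for k, v in ENDPOINT_TO_DVID.items()}

TABLE_COLUMNS = ["ID", "TIME", "DVID", "DV", "DOSE", "AUC", "SEX", "ARM"]


class TableError(ValueError):
    """An observation table violates the dialect invariants."""


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the ObservationTable invariants, raising with row numbers."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"missing required columns: {missing}")
    bad = table.index[~table["DVID"].isin(DVID_TO_ENDPOINT)]
    if len(bad):
        raise TableError(
            f"unknown DVID {table.loc[bad[0], 'DVID']!r} at row {bad[0] + 1} "
            f"(valid codes: {sorted(DVID_TO_ENDPOINT)})")
    bad = table.index[table["TIME"] < 0]
    if len(bad):
        raise TableError(f"negative TIME at row {bad[0] + 1}")
    dup = table.duplicated(subset=["ID", "TIME", "DVID"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise TableError(f"duplicate (ID, TIME, DVID) key at row {row + 1}")
    return table


def read_table(path) -> pd.DataFrame:
    """Read and validate an observation table CSV.

    Comma-delimited with header, '.' decimal; missing DV encoded as an
    empty field.  Raises :class:`TableError` naming the offending row on
    any invariant violation.
    """
    table = pd.read_csv(path, dtype={"SEX": str, "ARM": str})
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"missing required columns: {missing}")
    table["ID"] = table["ID"].astype(int)
    table["DVID"] = table["DVID"].astype(int)
    for col in ("TIME", "DV", "DOSE", "AUC"):
        table[col] = table[col].astype(float)
    return validate_table(table)


def write_table(table: pd.DataFrame, path) -> None:
    """Write an observation table in the canonical CSV form."""
    validate_table(pd.DataFrame(table))
    out = pd.DataFrame(table)[TABLE_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# configuration

#: config parameter key -> ModelParameters field
PARAM_KEY_MAP = {
    "LS_PRE": "LS_PRE",
    "LS_RBC": "LS_RBC",
    "RET_0": "RET_0",
    "RBC_0_male": "RBC_0",
    "RBC_diff_female": "RBC_diff_female",
    "MCH_0": "MCH_0",
    "IRF_0": "IRF_0",
    "Feedback": "gamma_FB",
    "k_TOL": "k_TOL",
    "Imax": "Imax",
    "AUC_50": "AUC50",
    "n_CTR": "n_CTR",
}

#: inverse map used when the IIV section names parameters by config key
IIV_KEY_MAP = {"LS_RBC": "LS_RBC", "RET_0": "RET_0", "RBC_0_male": "RBC_0",
               "MCH_0": "MCH_0", "IRF_0": "IRF_0", "AUC_50": "AUC50"}


def default_config() -> dict:
    """The full default configuration (typical male subject, trial design)."""
    return {
        "parameters": {
            "LS_PRE": 5.0, "LS_RBC": 125.0, "RET_0": 39.80,
            "RBC_0_male": 4.91, "RBC_diff_female": 1.59, "MCH_0": 29.80,
            "IRF_0": 0.0471, "Feedback": 2.42, "k_TOL": 0.022,
            "Imax": 0.6, "AUC_50": 16.50, "n_CTR": 4,
        },
        "iiv_cv": {"LS_RBC": 28.02, "RET_0": 26.02, "RBC_0_male": 5.34,
                   "MCH_0": 4.82, "IRF_0": 32.09, "AUC_50": 49.50},
        "residual": {
            "RET": {"kind": "proportional", "sd_prop": 0.22},
            "RBC": {"kind": "additive", "sd_add": 0.18},
            "MCH": {"kind": "additive", "sd_add": 0.35},
            "IRF": {"kind": "combined", "sd_add": 0.0096, "sd_prop": 0.38},
            "Hb_tot": {"kind": "additive", "sd_add": 3.0},
        },
        "design": {
            "arms": [[0, 15], [10, 17], [30, 16], [60, 14]],
            "t_on": 0.0, "t_off": 120.0,
            "visit_days": [0, 7, 14, 28, 42, 56, 70, 84, 98, 112, 119,
                           126, 140, 154, 168, 182, 196, 210, 224, 238],
            "c_exp": 1.1, "exposure_cv": 30.0, "sex_mix": 0.0,
        },
        "options": {
            "feedback_deficit_stimulates": True,
            "hb_chain": "mass",
            "ret_feedback": "release",
            "truncate_at_zero": False,
        },
    }


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise KeyError(
                f"invalid config key {path + key!r}; valid keys here: "
                f"{sorted(defaults)}")
        if isinstance(defaults[key], dict) and path != "residual.":
            if not isinstance(value, dict):
                raise KeyError(f"config section {path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            # residual specs are replaced wholesale (a kind change resets SDs)
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying it on the defaults.

    Unknown keys are rejected with the list of valid keys at that level.
    ``path=None`` returns the defaults.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise KeyError("config file must contain a top-level mapping")
    return _merge(cfg, user)


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def parameters_from_config(cfg: dict) -> ModelParameters:
    fields = {PARAM_KEY_MAP[k]: v for k, v in cfg["parameters"].items()}
    return ModelParameters(**fields)


def population_from_config(cfg: dict) -> PopulationModel:
    typical = parameters_from_config(cfg)
    iiv = {}
    for k, v in cfg["iiv_cv"].items():
        name = IIV_KEY_MAP.get(k, k)
        if not hasattr(typical, name):
            raise KeyError(f"invalid iiv_cv key {k!r}; valid: {sorted(IIV_KEY_MAP)}")
        iiv[name] = float(v)
    residual = {}
    for endpoint, spec in cfg["residual"].items():
        if endpoint not in ENDPOINT_TO_DVID:
            raise KeyError(f"invalid residual endpoint {endpoint!r}; "
                           f"valid: {sorted(ENDPOINT_TO_DVID)}")
        residual[endpoint] = ResidualSpec(**spec)
    return PopulationModel(typical=typical, iiv_cv=iiv, residual=residual,
                           truncate_at_zero=cfg["options"]["truncate_at_zero"])


def design_from_config(cfg: dict):
    from .trial import TrialDesign
    d = cfg["design"]
    return TrialDesign(arms=tuple((float(a), int(n)) for a, n in d["arms"]),
                       t_on=float(d["t_on"]), t_off=float(d["t_off"]),
                       visit_days=tuple(float(v) for v in d["visit_days"]),
                       c_exp=float(d["c_exp"]),
                       exposure_cv=float(d["exposure_cv"]),
                       sex_mix=float(d["sex_mix"]))
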