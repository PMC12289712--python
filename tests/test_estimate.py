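"""Likelihood machinery, pooled and two-stage estimators."""

import numpy as np
import pandas as pd
import pytest

from erythrosim import (ModelParameters, PooledMLEstimator, PopulationModel,
                        ResidualSpec, TrialDesign, TwoStageEstimator,
                        generate_trial, negloglik)

# additive-only specs: with prediction-independent variance the ML optimum
# on noiseless data sits exactly at the generating truth (a proportional
# term shifts it, since the log-variance term rewards smaller predictions)
ADD_SDS = {
    "RET": ResidualSpec("additive", sd_add=1.5),
    "RBC": ResidualSpec("additive", sd_add=0.18),
    "MCH": ResidualSpec("additive", sd_add=0.35),
    "IRF": ResidualSpec("additive", sd_add=0.0096),
    "Hb_tot": ResidualSpec("additive", sd_add=3.0),
}

SDS = {
    "RET": ResidualSpec("proportional", sd_prop=0.22),
    "RBC": ResidualSpec("additive", sd_add=0.18),
    "MCH": ResidualSpec("additive", sd_add=0.35),
    "IRF": ResidualSpec("combined", sd_add=0.0096, sd_prop=0.38),
    "Hb_tot": ResidualSpec("additive", sd_add=3.0),
}


def noiseless_trial(arms=((0.0, 1), (10.0, 1), (30.0, 1), (60.0, 1)),
                    seed=0, **design_kw):
    """Trial with no IIV, no residual noise and no exposure variability."""
    pop = PopulationModel(residual={k: ResidualSpec(v.kind, 0.0, 0.0)
                                    for k, v in SDS.items()}).zero_iiv()
    design = TrialDesign(arms=arms, exposure_cv=0.0, **design_kw)
    return generate_trial(design, pop, seed=seed, rtol=1e-10)


@pytest.fixture(scope="module")
def exact_data():
    table, _ = noiseless_trial()
    return table


class TestNegLogLik:

    def test_noiseless_data_gives_pure_normalization(self, exact_data,
                                                     typical):
        # zero residuals: -2LL reduces to sum(log(2 pi sigma^2))
        nll = negloglik(typical, exact_data, SDS, rtol=1e-9)
        d = exact_data.dropna(subset=["DV"])
        expected = 0.0
        for code, endpoint in [(1, "RET"), (2, "RBC"), (3, "MCH"), (4, "IRF")]:
            sub = d[d["DVID"] == code]
            # predictions at the truth equal the observations, so the
            # variance terms are evaluated at the observed values
            var = SDS[endpoint].variance(sub["DV"].to_numpy())
            expected += 0.5 * np.sum(np.log(2 * np.pi * var))
        assert nll == pytest.approx(expected, abs=1e-3)

    def test_doubling_additive_sd_costs_n_log2(self, exact_data, typical):
        res2 = dict(SDS)
        res2["RBC"] = ResidualSpec("additive", sd_add=2 * 0.18)
        n_rbc = (exact_data["DVID"] == 2).sum()
        nll1 = negloglik(typical, exact_data, SDS, rtol=1e-9)
        nll2 = negloglik(typical, exact_data, res2, rtol=1e-9)
        assert 2 * (nll2 - nll1) == pytest.approx(2 * n_rbc * np.log(2),
                                                  abs=1e-3)

    def test_truth_is_local_minimum_on_noiseless_data(self, exact_data,
                                                      typical):
        base = negloglik(typical, exact_data, SDS, rtol=1e-9)
        for name in ("LS_RBC", "RET_0", "MCH_0", "gamma_FB", "AUC50"):
            for factor in (0.9, 1.1):
                perturbed = typical.with_(
                    **{name: getattr(typical, name) * factor})
                assert negloglik(perturbed, exact_data, SDS,
                                 rtol=1e-9) > base + 1.0

    def test_degenerate_variance_is_penalized(self, exact_data, typical):
        # an all-zero residual spec makes the Gaussian density improper;
        # the evaluation must return the optimizer-safe penalty, not raise
        zero = {k: ResidualSpec(v.kind, 0.0, 0.0) for k, v in SDS.items()}
        val = negloglik(typical, exact_data, zero)
        assert val == pytest.approx(1e10)


class TestPooledFit:
    def test_self_recovery_on_exact_data(self):
        table, _ = noiseless_trial()
        est = PooledMLEstimator(
            free=("LS_RBC", "MCH_0", "gamma_FB", "AUC50"),
            residual=ADD_SDS, n_starts=1, seed=0,
            xatol=1e-6, fatol=1e-9, max_restarts=3, rtol=1e-8)
        est.fit(table)
        for name, truth in [("LS_RBC", 125.0), ("MCH_0", 29.8),
                            ("gamma_FB", 2.42), ("AUC50", 16.5)]:
            assert est.estimates_[name] == pytest.approx(truth, rel=1e-3), name

    def test_transform_invariance_on_single_parameter(self):
        table, _ = noiseless_trial(arms=((30.0, 2),))
        common = dict(free=("AUC50",), residual=SDS, n_starts=1,
                      xatol=1e-7, fatol=1e-10, max_restarts=3, rtol=1e-8,
                      start={"AUC50": 10.0})
        log_fit = PooledMLEstimator(**common).fit(table)
        nat_fit = PooledMLEstimator(transforms={"AUC50": "none"},
                                    **common).fit(table)
        assert log_fit.estimates_["AUC50"] == pytest.approx(
            nat_fit.estimates_["AUC50"], rel=1e-3)

    def test_estimated_residual_sd(self):
        pop = PopulationModel(residual=SDS).zero_iiv()
        design = TrialDesign(arms=((0.0, 20),), exposure_cv=0.0)
        table, _ = generate_trial(design, pop, seed=8)
        est = PooledMLEstimator(free=("sd_RBC_add",), residual=SDS,
                                n_starts=1, seed=0)
        est.fit(table)
        assert est.estimates_["sd_RBC_add"] == pytest.approx(0.18, rel=0.15)
        assert est.residual_["RBC"].sd_add == est.estimates_["sd_RBC_add"]

    def test_joint_imax_auc50_flagged_non_identifiable(self):
        # one dose level cannot separate Imax from AUC50
        table, _ = noiseless_trial(arms=((30.0, 3),))
        est = PooledMLEstimator(free=("Imax", "AUC50"), residual=SDS,
                                n_starts=1, maxfev=400, compute_se=True)
        est.fit(table)
        assert est.singular_info_ or est.condition_number_ > 1e4

    def test_predict_returns_per_record_predictions(self):
        table, _ = noiseless_trial()
        est = PooledMLEstimator(free=("MCH_0",), residual=SDS, n_starts=1,
                                maxfev=200)
        est.fit(table)
        pred = est.predict(table)
        assert {"ID", "TIME", "endpoint", "DV", "PRED"} <= set(pred.columns)
        mch = pred[pred["endpoint"] == "MCH"]
        assert np.allclose(mch["DV"], mch["PRED"], rtol=0.02)


class TestTwoStage:
    def test_zero_iiv_gives_agreeing_subjects_and_zero_cv(self):
        table, _ = noiseless_trial(arms=((0.0, 3),))
        est = TwoStageEstimator(free=("RET_0",), residual=ADD_SDS, maxfev=200)
        est.fit(table)
        assert est.per_subject_["RET_0"].std() < 1e-3
        assert est.iiv_cv_["RET_0"] < 0.5
        assert est.typical_["RET_0"] == pytest.approx(39.8, rel=1e-3)

    def test_recovers_baseline_iiv_cv(self, pop):
        # placebo subjects with IIV on RET_0 only: the two-stage %CV should
        # land near the generating 26.02
        quiet = PopulationModel(iiv_cv={"RET_0": 26.02}, residual=SDS)
        design = TrialDesign(arms=((0.0, 30),))
        table, _ = generate_trial(design, quiet, seed=17)
        est = TwoStageEstimator(free=("RET_0",), residual=SDS, maxfev=300)
        est.fit(table)
        assert est.iiv_cv_["RET_0"] == pytest.approx(26.02, abs=8.0)
        assert est.typical_["RET_0"] == pytest.approx(39.8, rel=0.15)

    def test_recovers_drug_potency_geometric_mean(self):
        # active subjects with IIV on AUC50 only (49.5 %CV)
        quiet = PopulationModel(iiv_cv={"AUC50": 49.50}, residual=SDS)
        design = TrialDesign(arms=((30.0, 12),), exposure_cv=0.0,
                             visit_days=(0.0, 14.0, 28.0, 56.0, 84.0, 112.0,
                                         119.0, 140.0, 168.0))
        table, _ = generate_trial(design, quiet, seed=23)
        est = TwoStageEstimator(free=("AUC50",), residual=SDS, maxfev=300)
        est.fit(table)
        assert est.typical_["AUC50"] == pytest.approx(16.5, rel=0.25)
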