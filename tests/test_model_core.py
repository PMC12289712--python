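"""Structural model: derived rates, steady state, drug effect, feedback, RHS."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from erythrosim import (IntegrationError, MechanismSpec, ModelParameters,
                        ParameterError, DegenerateStateError, derive_rates,
                        inhibition, observe, rhs, steady_state, stimulation,
                        tolerance_modulation)
from erythrosim._kernel import (IDX_HB, IDX_RBC, IDX_RET_IMM_BL,
                                IDX_RET_MAT_BL, IDX_TOL2,
                                integrate_population)


def params_strategy():
    return st.builds(
        ModelParameters,
        LS_RBC=st.floats(60, 200),
        RET_0=st.floats(15, 90),
        RBC_0=st.floats(3.5, 6.0),
        MCH_0=st.floats(22, 36),
        IRF_0=st.floats(0.01, 0.25),
        gamma_FB=st.floats(0.0, 6.0),
        k_TOL=st.floats(0.0, 0.1),
        AUC50=st.floats(2.0, 60.0),
    )


class TestDeriveRates:
    def test_transit_rate_from_lifespan(self, rates):
        # 4 transit compartments over a 125-day erythrocyte lifespan
        assert rates.k_RBC == pytest.approx(0.032)
        assert rates.k_PRE == pytest.approx(1 / 5)

    def test_reticulocyte_rate_flux_balance(self, typical, rates):
        # k_RET must balance marrow outflow with erythrocyte-side elimination:
        # k_RET*RET_0*(1-IRF_0) = k_RBC*RBC_0/n_CTR (on the 1e9/L scale)
        lhs = rates.k_RET * typical.RET_0 * (1 - typical.IRF_0)
        rhs_flux = rates.k_RBC * typical.RBC_0 * 1e3 / typical.n_CTR
        assert lhs == pytest.approx(rhs_flux, rel=1e-12)
        assert rates.k_RET == pytest.approx(1.0357, rel=1e-4)

    def test_no_premature_release_limit(self, typical):
        r = derive_rates(typical.with_(IRF_0=1e-12))
        assert r.p_release == pytest.approx(0.0, abs=1e-11)

    @given(params_strategy())
    def test_flux_balance_property(self, p):
        r = derive_rates(p)
        assert r.k_RET * p.RET_0 * (1 - p.IRF_0) == pytest.approx(r.F0, rel=1e-12)
        assert r.Hb_0 == pytest.approx(p.RBC_0 * p.MCH_0)
        assert 0 <= r.p_release

    @pytest.mark.parametrize("field,value", [
        ("LS_RBC", 0.0), ("LS_PRE", -1.0), ("RET_0", 0.0), ("RBC_0", -2.0),
        ("MCH_0", 0.0), ("AUC50", 0.0), ("IRF_0", 0.0), ("IRF_0", 1.0),
        ("Imax", 1.5), ("gamma_FB", -0.1), ("k_TOL", -0.01), ("n_CTR", 0),
    ])
    def test_validation_names_offending_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            ModelParameters(**{field: value})


class TestSteadyState:
    def test_reproduces_reported_baselines(self, typical, baseline_state):
        out = observe(baseline_state)
        assert out.RET == pytest.approx(39.80, rel=1e-12)
        assert out.RBC == pytest.approx(4.91, rel=1e-12)
        assert out.MCH == pytest.approx(29.80, rel=1e-12)
        assert out.IRF == pytest.approx(0.0471, rel=1e-12)
        assert out.Hb_tot == pytest.approx(146.318, rel=1e-12)

    def test_is_equilibrium(self, typical, baseline_state):
        dy = rhs(0.0, baseline_state, typical)
        scale = np.abs(baseline_state).max()
        assert np.abs(dy).max() < 1e-12 * scale

    @given(params_strategy())
    def test_equilibrium_property(self, p):
        y = steady_state(p)
        out = observe(y)
        assert out.RET == pytest.approx(p.RET_0, rel=1e-10)
        assert out.IRF == pytest.approx(p.IRF_0, rel=1e-10)
        dy = rhs(0.0, y, p)
        assert np.abs(dy).max() < 1e-10 * np.abs(y).max()

    def test_equilibrium_preserved_over_240_days(self, typical):
        grid = np.arange(0.0, 241.0, 10.0)
        traj = integrate_population([typical], [0.0], "none", grid, rtol=1e-10)
        out = observe(traj[0])
        for value, base in [(out.RET, 39.80), (out.RBC, 4.91),
                            (out.MCH, 29.80), (out.IRF, 0.0471)]:
            assert np.max(np.abs(value / base - 1)) < 1e-8


class TestInhibition:
    @pytest.mark.parametrize("mult,expected", [(0.5, 0.20), (2.0, 0.40)])
    def test_reported_exposure_response(self, mult, expected):
        assert inhibition(mult * 16.5, 0.6, 16.5) == pytest.approx(expected)

    def test_limits(self):
        assert inhibition(0.0, 0.6, 16.5) == 0.0
        assert inhibition(1e12, 0.6, 16.5) == pytest.approx(0.6, rel=1e-6)

    def test_treatment_window(self):
        assert inhibition(33.0, 0.6, 16.5, t=50.0) == pytest.approx(0.4)
        assert inhibition(33.0, 0.6, 16.5, t=120.0) == 0.0
        assert inhibition(33.0, 0.6, 16.5, t=-1.0) == 0.0

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_monotone_and_bounded(self, a1, a2):
        lo, hi = sorted((a1, a2))
        i_lo = inhibition(lo, 0.6, 16.5)
        i_hi = inhibition(hi, 0.6, 16.5)
        assert 0.0 <= i_lo <= i_hi <= 0.6

    def test_invalid_exposure(self):
        with pytest.raises(ParameterError):
            inhibition(-1.0, 0.6, 16.5)


class TestStimulation:
    def test_neutral_at_baseline(self):
        assert stimulation(146.318, 146.318, 2.42) == pytest.approx(1.0)

    def test_deficit_stimulates(self):
        # 10 % hemoglobin deficit with the typical feedback exponent
        got = stimulation(0.9 * 146.318, 146.318, 2.42)
        assert got == pytest.approx(np.exp(0.242), rel=1e-12)
        assert got > 1

    def test_disabled_flag_and_zero_gamma(self):
        assert stimulation(50.0, 146.0, 2.42, feedback_disabled=True) == 1.0
        assert stimulation(50.0, 146.0, 0.0) == 1.0

    def test_literal_sign_option_suppresses_on_deficit(self):
        got = stimulation(0.9 * 146.0, 146.0, 2.42, deficit_stimulates=False)
        assert got == pytest.approx(np.exp(-0.242), rel=1e-12)

    def test_invalid_baseline(self):
        with pytest.raises(ParameterError):
            stimulation(100.0, 0.0, 2.42)


class TestToleranceModulation:
    def test_baseline_and_doubling(self):
        assert tolerance_modulation(196.4, 196.4) == pytest.approx(1.0)
        assert tolerance_modulation(2 * 196.4, 196.4) == pytest.approx(0.5)

    def test_floor_clamp_warns(self, caplog):
        with caplog.at_level("WARNING"):
            got = tolerance_modulation(0.0, 196.4)
        assert "clamped" in caplog.text
        assert got == pytest.approx(1e9, rel=1e-6)

    def test_frozen_tolerance_states(self, typical):
        # k_TOL = 0 freezes TOL at PRE_0 so the modulation stays 1 and a
        # drug-free trajectory stays put
        p = typical.with_(k_TOL=0.0)
        y = steady_state(p)
        dy = rhs(0.0, y, p)
        assert np.abs(dy).max() < 1e-12


class TestObserve:
    def test_reported_baseline_mch(self, baseline_state):
        assert observe(baseline_state).MCH == pytest.approx(29.80)

    def test_zero_hemoglobin(self, baseline_state):
        y = baseline_state.copy()
        y[IDX_HB] = 0.0
        out = observe(y)
        assert out.Hb_tot == 0.0 and out.MCH == 0.0

    def test_mch_ratio_identity(self, baseline_state):
        y = baseline_state.copy()
        y[IDX_RBC] = 2 * y[IDX_RBC]
        out0, out = observe(baseline_state), observe(y)
        assert out.MCH == pytest.approx(out0.MCH / 2)
        assert out.Hb_tot == pytest.approx(out0.Hb_tot)

    def test_degenerate_state_rejected(self, baseline_state):
        y = baseline_state.copy()
        y[IDX_RET_IMM_BL] = 0.0
        y[IDX_RET_MAT_BL] = 0.0
        with pytest.raises(DegenerateStateError):
            observe(y)


class TestRhs:
    def test_mechanism_b_onset_sign(self, typical, baseline_state):
        # just after treatment start only precursor inflow is reduced
        mech = MechanismSpec("B", 33.0)
        dy = rhs(0.0, baseline_state, typical, mech=mech)
        assert dy[0] < 0
        assert np.abs(dy[1:]).max() < 1e-12 * np.abs(baseline_state).max()

    def test_mechanism_c_onset_sign(self, typical, baseline_state):
        dy = rhs(0.0, baseline_state, typical, mech=MechanismSpec("C", 33.0))
        assert dy[0] > 0          # precursors accumulate
        assert dy[3] < 0          # marrow reticulocyte inflow drops

    def test_gamma_zero_decouples_counts_under_mechanism_a(self, typical):
        p = typical.with_(gamma_FB=0.0)
        grid = np.arange(0.0, 1251.0, 25.0)
        traj = integrate_population([p], [33.0], "A", grid, t_off=1250.0,
                                    rtol=1e-10)
        out = observe(traj[0])
        # cell counts never move; hemoglobin decays to the inhibited level
        assert np.max(np.abs(out.RBC / 4.91 - 1)) < 1e-8
        assert np.max(np.abs(out.RET / 39.8 - 1)) < 1e-8
        hb_limit = 0.6 * 29.8 * 4.91 / 4
        assert traj[0][-1, IDX_HB] == pytest.approx(
            [hb_limit] * 4, rel=5e-3)

    def test_state_guards(self, typical, baseline_state):
        bad = baseline_state.copy()
        bad[0] = np.nan
        with pytest.raises(IntegrationError):
            rhs(0.0, bad, typical)
        bad = baseline_state.copy()
        bad[0] = -1.0
        with pytest.raises(IntegrationError):
            rhs(0.0, bad, typical)


@pytest.fixture(scope="module")
def fine_traj(typical):
    grid = np.arange(0.0, 40.0, 0.25)
    traj = integrate_population([typical], [33.0], "A", grid, rtol=1e-10)
    return grid, traj[0]


class TestConservation:
    """Mass-balance identities checked against finite differences of a
    perturbed trajectory (mechanism A, active feedback)."""

    def test_hemoglobin_mass_balance(self, typical, fine_traj):
        grid, y = fine_traj
        r = derive_rates(typical)
        hb_tot = y[:, IDX_HB].sum(axis=1)
        # blood-side maturation is not scaled by the feedback
        inflow = r.k_RET * y[:, IDX_RET_MAT_BL] * 1e-3
        i = inhibition(33.0, typical.Imax, typical.AUC50)
        expected = typical.MCH_0 * (1 - i) * inflow - r.k_RBC * y[:, IDX_HB][:, -1]
        fd = np.gradient(hb_tot, grid)
        mask = slice(2, -2)
        assert np.allclose(fd[mask], expected[mask], rtol=5e-3,
                           atol=1e-4 * np.abs(expected).max())

    def test_cell_conservation(self, typical, fine_traj):
        grid, y = fine_traj
        r = derive_rates(typical)
        rbc_tot = y[:, IDX_RBC].sum(axis=1)
        inflow = r.k_RET * y[:, IDX_RET_MAT_BL] * 1e-3
        expected = inflow - r.k_RBC * y[:, IDX_RBC][:, -1]
        fd = np.gradient(rbc_tot, grid)
        mask = slice(2, -2)
        assert np.allclose(fd[mask], expected[mask], rtol=5e-3,
                           atol=5e-4 * np.abs(expected).max())


class TestIrfAlgebra:
    def test_steady_state_irf_vs_linear_system_oracle(self):
        # brute-force oracle: solve the 4-pool reticulocyte linear system at
        # steady state for random release fractions and rates
        rng = np.random.default_rng(12345)
        for _ in range(25):
            p = rng.uniform(0.005, 0.4)
            k = rng.uniform(0.2, 3.0)
            flux = rng.uniform(5.0, 80.0)
            M = np.array([
                [-k, 0.0, 0.0, 0.0],
                [p * k, -k, 0.0, 0.0],
                [(1 - p) * k, 0.0, -k, 0.0],
                [0.0, k, k, -k],
            ])
            x = np.linalg.solve(M, np.array([-flux, 0.0, 0.0, 0.0]))
            irf = x[1] / (x[1] + x[3])
            assert irf == pytest.approx(p / (1 + p), rel=1e-12)

    def test_model_pools_match_oracle(self, typical, rates, baseline_state):
        irf0 = typical.IRF_0
        p = rates.p_release
        blood = baseline_state[IDX_RET_IMM_BL] + baseline_state[IDX_RET_MAT_BL]
        assert baseline_state[IDX_RET_IMM_BL] / blood == pytest.approx(
            p / (1 + p), rel=1e-12)
        assert p / (1 + p) == pytest.approx(irf0, rel=1e-12)


class TestFeedbackPlacement:
    def test_variants_identical_at_baseline(self, typical):
        grid = np.arange(0.0, 241.0, 20.0)
        for variant in ("release", "uniform"):
            traj = integrate_population([typical], [0.0], "none", grid,
                                        rtol=1e-10, ret_feedback=variant)
            out = observe(traj[0])
            assert np.max(np.abs(out.Hb_tot / 146.318 - 1)) < 1e-8

    def test_variants_differ_under_stimulation(self, typical):
        # uniform scaling cancels out of the standing blood count, marrow
        # release scaling does not
        grid = np.arange(0.0, 121.0, 5.0)
        rel = integrate_population([typical], [33.0], "A", grid,
                                   ret_feedback="release")
        uni = integrate_population([typical], [33.0], "A", grid,
                                   ret_feedback="uniform")
        ret_rel = observe(rel[0]).RET[-1]
        ret_uni = observe(uni[0]).RET[-1]
        assert ret_rel > 1.2 * 39.8      # sustained reticulocytosis
        assert ret_uni < ret_rel


class TestContentChain:
    def test_content_chain_matches_mass_chain_at_baseline(self, typical):
        grid = np.arange(0.0, 121.0, 5.0)
        kwargs = dict(t_grid=grid, rtol=1e-10)
        mass = integrate_population([typical], [0.0], "none",
                                    hb_mode="mass", **kwargs)
        content = integrate_population([typical], [0.0], "none",
                                       hb_mode="content", **kwargs)
        out_m = observe(mass[0], hb_mode="mass")
        out_c = observe(content[0], hb_mode="content")
        assert np.allclose(out_m.Hb_tot, out_c.Hb_tot, rtol=1e-8)
        assert np.allclose(out_m.MCH, out_c.MCH, rtol=1e-8)
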