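"""Normalized-Hill cascade model: inputs, dynamics, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from epiderk import (
    CascadeParameters,
    NormalizedHillParams,
    ca_input,
    cam_input,
    f_act,
    knockout_cam,
    rhs,
    sample_random_parameters,
    solve_steady_state,
    spatial_profile,
    steady_state_root,
    volume_ratio,
)
from epiderk.cascade import _integrate_to_steady, _steady_states_fast
from epiderk.exceptions import DomainError, ParameterError


class TestNormalizedHill:
    def test_normalization_constraints(self):
        h = NormalizedHillParams()
        assert f_act(0.0, h) == pytest.approx(0.0, abs=1e-12)
        assert f_act(h.ec50, h) == pytest.approx(0.5, abs=1e-12)
        assert f_act(1.0, h) == pytest.approx(1.0, abs=1e-12)

    def test_derived_constants_match_root_finding_oracle(self):
        """B and K from the closed form agree with an independent numeric
        solution of the two constraint equations."""
        h = NormalizedHillParams()  # n=1.4, ec50=0.5

        # oracle: for a trial K, B = K^n + 1 enforces f(1)=1; find K such
        # that f(ec50) = 1/2 by bisection, independent of the closed form.
        def half_max_gap(K):
            B = K**h.n + 1.0
            return B * h.ec50**h.n / (K**h.n + h.ec50**h.n) - 0.5

        K_oracle = brentq(half_max_gap, 1e-3, 1e3, xtol=1e-14)
        assert h.K == pytest.approx(K_oracle, abs=1e-10)
        assert h.B == pytest.approx(K_oracle**h.n + 1.0, rel=1e-10)
        assert h.B == pytest.approx(2.5649, abs=1e-4)
        assert h.K == pytest.approx(1.3770, abs=1e-4)

    def test_intermediate_value_against_direct_evaluation(self):
        h = NormalizedHillParams()
        expected = h.B * 0.25**h.n / (h.K_pow_n + 0.25**h.n)
        assert 0.0 < expected < 0.5
        assert f_act(0.25, h) == pytest.approx(expected)

    def test_degenerate_ec50_rejected(self):
        with pytest.raises(ParameterError):
            NormalizedHillParams(n=1.0, ec50=0.5)  # 2*ec50^n == 1

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_monotone_increasing(self, x1, x2):
        h = NormalizedHillParams()
        lo, hi = sorted((x1, x2))
        if lo < hi:
            assert f_act(lo, h) < f_act(hi, h)


class TestInputs:
    B_CA, A_CA = 0.754, 0.092
    B_CAM, A_CAM = 0.363, 0.485

    def test_ca_profile_values(self):
        assert ca_input(0.0, self.B_CA, self.A_CA) == pytest.approx(0.754)
        assert ca_input(5.0, self.B_CA, self.A_CA) == pytest.approx(0.846)
        assert ca_input(7.0, self.B_CA, self.A_CA) == pytest.approx(self.B_CA)

    def test_ca_peaks_at_granular_transitional_interface(self):
        d = np.linspace(0, 7, 701)
        ca = ca_input(d, self.B_CA, self.A_CA)
        assert d[np.argmax(ca)] == pytest.approx(5.0)
        assert np.max(np.abs(np.diff(ca))) < 0.01  # continuous

    def test_cam_profile_values(self):
        assert cam_input(0.0, self.B_CAM, self.A_CAM) == pytest.approx(0.6055)
        # continuous at d=1 from both branches
        assert cam_input(1.0 - 1e-9, self.B_CAM, self.A_CAM) == pytest.approx(
            cam_input(1.0, self.B_CAM, self.A_CAM), abs=1e-6
        )
        assert cam_input(1.0, self.B_CAM, self.A_CAM) == pytest.approx(
            self.B_CAM + self.A_CAM
        )
        # baseline on the transitional plateau; finite jump at d=5
        assert cam_input(5.0, self.B_CAM, self.A_CAM) == pytest.approx(self.B_CAM)
        left = cam_input(5.0 - 1e-12, self.B_CAM, self.A_CAM)
        assert left == pytest.approx(self.B_CAM + self.A_CAM * np.exp(-4.0), rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ca_input(7.5, 0.5, 0.1)
        with pytest.raises(DomainError):
            cam_input(-0.1, 0.5, 0.1)

    def test_volume_ratio_linear(self, default_params):
        assert volume_ratio(0.0, default_params) == pytest.approx(2.0)
        assert volume_ratio(7.0, default_params) == pytest.approx(5.0)
        assert volume_ratio(3.5, default_params) == pytest.approx(3.5)


class TestRhs:
    def test_zero_state_zero_drive_is_fixed_point(self):
        p = CascadeParameters(b_ca=0.0, a_ca=0.0)
        assert np.allclose(rhs(np.zeros(5), 3.0, p), 0.0)

    def test_rafc_drive_clamped_at_zero(self):
        """When inhibition outweighs activation the Rafc production term is
        clamped: dRafc/dt reduces to pure decay."""
        # strong CaM, weak Ca: f(Ca)*w - f(CaM)*w < 0 at d=0
        p = CascadeParameters(b_ca=0.1, a_ca=0.0, b_cam=0.9, a_cam=0.0)
        state = np.array([0.4, 0.0, 0.0, 0.0, 0.0])
        d = rhs(state, 0.0, p)
        assert d[0] == pytest.approx(-0.4 / p.tau_rafc)

    def test_shuttle_flux_bookkeeping(self, default_params):
        """The r-scaled shuttle terms balance: the nuclear import term equals
        r times the cytoplasmic export term, and symmetrically for export."""
        p = default_params
        rng = np.random.default_rng(1)
        state = rng.uniform(0.1, 0.9, size=5)
        depth = 2.0
        r = volume_ratio(depth, p)
        rafc, mekc, mekn, erkc, erkn = state
        full = rhs(state, depth, p)
        # subtract the shuttle-free parts computed with shuttling disabled
        p0 = p.replace(s_mekcn=0.0, s_meknc=0.0, s_erkcn=0.0, s_erknc=0.0)
        base = rhs(state, depth, p0)
        shuttle = full - base
        assert shuttle[2] * p.tau_mekn == pytest.approx(
            -(shuttle[1] * p.tau_mekc) * r
        )
        assert shuttle[4] * p.tau_erkn == pytest.approx(
            -(shuttle[3] * p.tau_erkc) * r
        )


class TestSteadyState:
    def test_no_drive_gives_zero_steady_state(self):
        p = CascadeParameters(b_ca=0.0, a_ca=0.0)
        res = solve_steady_state(3.0, p)
        assert res.converged
        assert np.allclose(res.state.as_array(), 0.0, atol=1e-8)

    def test_erk_higher_at_calcium_peak_than_basal(self, default_params):
        lo = solve_steady_state(0.0, default_params).state
        hi = solve_steady_state(5.0, default_params).state
        assert hi.erkc > lo.erkc
        assert hi.erkn > lo.erkn

    def test_integrator_routes_and_root_agree(self, default_params):
        """Adaptive RK23, fixed-step RK4 and the algebraic root coincide."""
        for d in (0.5, 2.5, 5.0, 7.0):
            adaptive = solve_steady_state(d, default_params)
            assert adaptive.converged
            fixed, _ = _integrate_to_steady(np.array([d]), default_params)
            alg = steady_state_root(d, default_params)
            assert np.allclose(adaptive.state.as_array(), fixed[:, 0], atol=1e-5)
            assert np.allclose(adaptive.state.as_array(), alg.as_array(), atol=1e-5)

    def test_random_parameters_bounded_and_ic_independent(self):
        rng = np.random.default_rng(20)
        depths = np.array([0.0, 1.75, 3.5, 5.25, 7.0])
        for _ in range(10):
            p = sample_random_parameters(rng)
            # slowly damped sets need more than the default 50 time units;
            # early exit keeps converged sets cheap
            from_zero, res0 = _integrate_to_steady(depths, p, t_final=2000.0)
            from_max, res1 = _integrate_to_steady(
                depths, p, t_final=2000.0,
                x0=np.repeat(p.xmax_vector()[:, None], depths.size, 1),
            )
            assert np.max(res0) < 1e-6 and np.max(res1) < 1e-6
            assert np.max(np.abs(from_zero - from_max)) < 1e-5
            assert np.all(from_zero >= -1e-9)
            assert np.all(from_zero <= p.xmax_vector()[:, None] + 1e-9)

    def test_fast_path_matches_integrator(self, default_params):
        depths = np.arange(7) + 0.5
        fast, _ = _steady_states_fast(depths, default_params)
        slow, _ = _integrate_to_steady(depths, default_params)
        assert np.max(np.abs(fast - slow)) < 1e-5

    def test_removing_erk_feedback_weakly_increases_rafc(self, default_params):
        base = spatial_profile(default_params)
        no_fb = spatial_profile(default_params.replace(w_erkc_rafc=0.0))
        assert np.all(no_fb.species("rafc") >= base.species("rafc") - 1e-12)


class TestSpatialProfile:
    def test_default_grid_has_15_locations(self, default_params):
        prof = spatial_profile(default_params)
        assert prof.depths.size == 15
        assert prof.depths[0] == 0.0 and prof.depths[-1] == 7.0
        assert prof.converged.all()

    def test_step_one_gives_8_points(self, default_params):
        assert spatial_profile(default_params, step=1.0).depths.size == 8

    def test_bad_step_rejected(self, default_params):
        with pytest.raises(DomainError):
            spatial_profile(default_params, step=0.3)

    def test_erkn_nondecreasing_over_spinous_granular(self, default_params):
        prof = spatial_profile(default_params)
        sel = (prof.depths >= 1.0) & (prof.depths <= 5.0)
        erkn = prof.species("erkn")[sel]
        assert np.all(np.diff(erkn) >= -1e-12)


class TestKnockout:
    def test_knockout_increases_erk_everywhere(self, default_params):
        base = spatial_profile(default_params)
        ko = spatial_profile(knockout_cam(default_params))
        assert np.all(ko.species("erkc") >= base.species("erkc") - 1e-12)
        assert np.all(ko.species("erkn") >= base.species("erkn") - 1e-12)

    def test_idempotent(self, default_params):
        once = knockout_cam(default_params)
        assert knockout_cam(once) == once

    def test_noop_without_cam_input(self):
        p = CascadeParameters(b_cam=0.0, a_cam=0.0)
        prof = spatial_profile(p)
        prof_ko = spatial_profile(knockout_cam(p))
        assert np.allclose(prof.states, prof_ko.states, atol=1e-12)
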