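import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import occupet as op
from occupet.errors import DomainError, InsufficientDataError
from occupet.kinetics import frame_weights

rates = st.floats(min_value=0.02, max_value=2.0)


class TestImpulseResponse:
    def test_reduces_to_1tcm_when_k3_zero(self):
        p = op.KineticParams(K1=0.15, k2=0.3, k3=0.0, k4=0.0)
        assert op.impulse_response_2tcm(p) == [(0.15, 0.3)]

    def test_quadratic_roots_hand_checked(self):
        # theta^2 - (k2+k3+k4) theta + k2 k4 = 0 for (0.4, 0.3, 0.15)
        p = op.KineticParams(K1=0.2, k2=0.4, k3=0.3, k4=0.15)
        (phi1, th1), (phi2, th2) = op.impulse_response_2tcm(p)
        assert th1 == pytest.approx(0.77231, abs=1e-4)
        assert th2 == pytest.approx(0.07769, abs=1e-4)
        assert phi1 + phi2 == pytest.approx(p.K1, rel=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(K1=rates, k2=rates, k3=rates, k4=rates)
    def test_integral_of_h_equals_vt(self, K1, k2, k3, k4):
        """∫h dt = (K1/k2)(1 + k3/k4): symbolic identity vs quadrature."""
        p = op.KineticParams(K1=K1, k2=k2, k3=k3, k4=k4)
        modes = op.impulse_response_2tcm(p)
        analytic = sum(phi / th for phi, th in modes)
        vt = op.derive_macro(p).V_T
        assert analytic == pytest.approx(vt, rel=1e-10)
        numeric, _ = quad(
            lambda t: sum(phi * np.exp(-th * t) for phi, th in modes), 0, np.inf
        )
        assert numeric == pytest.approx(vt, rel=1e-7)

    def test_irreversible_limit(self):
        # k4 = 0: one mode decays, the other is a constant trapping term
        p = op.KineticParams(K1=0.2, k2=0.4, k3=0.2, k4=0.0)
        modes = sorted(op.impulse_response_2tcm(p), key=lambda m: m[1])
        assert modes[0][1] == pytest.approx(0.0, abs=1e-12)
        assert modes[0][0] == pytest.approx(0.2 * 0.2 / 0.6, rel=1e-10)


class TestDeriveMacro:
    def test_hand_arithmetic(self):
        m = op.derive_macro(op.KineticParams(K1=0.2, k2=0.4, k3=0.3, k4=0.15))
        assert m.BP_ND == pytest.approx(2.0)
        assert m.V_T == pytest.approx(1.5)

    def test_k3_zero(self):
        m = op.derive_macro(op.KineticParams(K1=0.2, k2=0.4, k3=0.0, k4=0.15))
        assert m.BP_ND == 0.0 and m.V_T == pytest.approx(0.5)

    def test_control_macro_implies_k1_over_k2(self, control_params):
        # V_T = 0.87 with BP = 1.85 pins K1/k2 at 0.87/2.85
        assert control_params.K1 / control_params.k2 == pytest.approx(0.87 / 2.85)
        m = op.derive_macro(control_params)
        assert m.V_T == pytest.approx(0.87) and m.BP_ND == pytest.approx(1.85)

    def test_undefined_for_zero_k4(self):
        with pytest.raises(DomainError):
            op.derive_macro(op.KineticParams(K1=0.2, k2=0.4, k3=0.2, k4=0.0))


class TestFitCompartment:
    def test_noiseless_recovery(self, noiseless_control_tac, control_params, analytic_grid):
        """Exact-model recovery: every rate within 1%, Vb within 0.005, and
        the macro-parameters land on the generating control values."""
        fit = op.fit_compartment(
            noiseless_control_tac, None, model="2TRCM", input_grid=analytic_grid
        )
        assert fit.converged
        for name in ("K1", "k2", "k3", "k4"):
            est, tru = getattr(fit.params, name), getattr(control_params, name)
            assert est == pytest.approx(tru, rel=0.01), name
        assert fit.params.Vb == pytest.approx(control_params.Vb, abs=0.005)
        assert fit.macro.V_T == pytest.approx(0.87, rel=0.01)
        assert fit.macro.BP_ND == pytest.approx(1.85, rel=0.01)

    def test_scale_equivariance(self, control_params, input_params, schedule):
        """Multiplying input and TAC by a common factor leaves rate constants
        unchanged."""
        tac = op.simulate_tac(control_params, input_params, schedule)
        t, cp, wb = op.analytic_input_grid(input_params, schedule)
        fit1 = op.fit_compartment(tac, None, model="2TRCM", input_grid=(t, cp, wb))
        s = 4.2
        tac2 = op.TimeActivityCurve(schedule, s * tac.activity)
        fit2 = op.fit_compartment(tac2, None, model="2TRCM", input_grid=(t, s * cp, s * wb))
        for name in ("K1", "k2", "k3", "k4", "Vb"):
            assert getattr(fit2.params, name) == pytest.approx(
                getattr(fit1.params, name), rel=1e-3
            ), name

    def test_1tcm_fit_on_1tcm_data(self, input_params, schedule, analytic_grid):
        p = op.KineticParams(K1=0.15, k2=0.25, Vb=0.05)
        tac = op.simulate_tac(p, input_params, schedule)
        fit = op.fit_compartment(tac, None, model="1TCM", input_grid=analytic_grid)
        assert fit.params.K1 == pytest.approx(0.15, rel=0.01)
        assert fit.params.k2 == pytest.approx(0.25, rel=0.01)
        assert fit.macro.BP_ND == 0.0

    def test_sampled_blood_path(self, noiseless_control_tac, corrected_blood):
        # realistic path: input rebuilt from 15 arterial samples; small
        # interpolation bias is expected but macro-parameters stay close
        fit = op.fit_compartment(noiseless_control_tac, corrected_blood, model="2TRCM")
        assert fit.converged
        assert fit.macro.V_T == pytest.approx(0.87, rel=0.05)
        assert fit.macro.BP_ND == pytest.approx(1.85, rel=0.08)


class TestAkaike:
    def _result(self, model, wrss, n=21):
        r = op.FitResult(model=model, params=op.KineticParams(0.1, 0.2), macro=None)
        r.wrss, r.n_frames, r.converged = wrss, n, True
        return r

    def test_lower_wrss_lower_aic(self):
        assert op.akaike(self._result("2TRCM", 1.0)) < op.akaike(self._result("2TRCM", 2.0))

    def test_parameter_penalty(self):
        # identical WRSS: the 5-parameter model pays exactly 2 * dP = 4
        a1 = op.akaike(self._result("1TCM", 1.5))
        a2 = op.akaike(self._result("2TRCM", 1.5))
        assert a2 - a1 == pytest.approx(4.0)

    def test_zero_wrss_sentinel(self):
        with pytest.warns(UserWarning):
            assert op.akaike(self._result("1TCM", 0.0)) < -1e9

    def test_weights_decrease_with_decay(self, schedule):
        w = frame_weights(schedule, np.log(2) / 20.38)
        # long late frames are still down-weighted relative to their duration
        w_per_dur = w / schedule.duration_min
        assert np.all(np.diff(w_per_dur) <= 1e-12)


class TestBiExponential:
    @staticmethod
    def _curve(schedule, hl_fast=10.0, hl_slow=129.0, frac_fast=0.10, scale=50.0):
        mids = schedule.mid_min
        lf, ls = np.log(2) / hl_fast, np.log(2) / hl_slow
        t0 = 2.0
        y = scale * (
            frac_fast * np.exp(-lf * (mids - t0)) + (1 - frac_fast) * np.exp(-ls * (mids - t0))
        )
        y[mids < t0] = scale  # flat before the window; never used by the fit
        return op.TimeActivityCurve(schedule, y)

    def test_recovery_of_control_half_lives(self, schedule):
        """Exact two-exponential washout with 10/129-min half-lives and
        10/90% shares is recovered within 2%."""
        tac = self._curve(schedule)
        fit = op.fit_biexponential(tac, window_min=(2.0, 60.0))
        assert not fit.degenerate
        assert fit.half_life_fast == pytest.approx(10.0, rel=0.02)
        assert fit.half_life_slow == pytest.approx(129.0, rel=0.02)
        assert fit.fraction_fast == pytest.approx(10.0, rel=0.05)
        assert fit.fraction_slow == pytest.approx(90.0, rel=0.05)

    def test_grid_search_oracle(self, schedule):
        """Brute-force lattice over (rate_fast, rate_slow) agrees with the
        nonlinear fit on which rate pair explains the curve."""
        tac = self._curve(schedule)
        mids = schedule.mid_min
        sel = (mids >= 2.0) & (mids <= 60.0)
        t, y = mids[sel] - mids[sel][0], tac.activity[sel]
        best = (np.inf, None)
        for lf in np.geomspace(0.01, 0.3, 40):
            for ls in np.geomspace(0.001, 0.02, 40):
                if ls >= lf:
                    continue
                A = np.vstack([np.exp(-lf * t), np.exp(-ls * t)]).T
                coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = float(np.sum((A @ coef - y) ** 2))
                if rss < best[0]:
                    best = (rss, (np.log(2) / lf, np.log(2) / ls))
        hl_fast, hl_slow = best[1]
        fit = op.fit_biexponential(tac, window_min=(2.0, 60.0))
        assert fit.half_life_fast == pytest.approx(hl_fast, rel=0.10)
        assert fit.half_life_slow == pytest.approx(hl_slow, rel=0.10)

    def test_mono_exponential_degenerates(self, schedule):
        mids = schedule.mid_min
        y = 30.0 * np.exp(-np.log(2) / 40.0 * mids)
        tac = op.TimeActivityCurve(schedule, y)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = op.fit_biexponential(tac, window_min=(2.0, 60.0))
        assert fit.degenerate
        assert fit.half_life_slow == pytest.approx(40.0, rel=0.02)

    def test_too_few_frames(self, schedule):
        tac = self._curve(schedule)
        with pytest.raises(InsufficientDataError):
            op.fit_biexponential(tac, window_min=(55.0, 60.0))
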