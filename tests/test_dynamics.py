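"""Single-oscillator model: branch functions, RK4 integration, regime
classification and threshold localization."""

import numpy as np
import pytest
from scipy import optimize

from epileptornet.dynamics import (
    DEFAULT_INIT,
    EpileptorState,
    ModelParams,
    Trajectory,
    classify_regime,
    derivatives,
    f1,
    f2,
    find_threshold,
    integrate,
    sle_signal,
)
from epileptornet.errors import (
    BracketError,
    DomainError,
    InsufficientDataError,
    IntegrationBlowupError,
    ParameterError,
)


class TestModelParams:
    def test_defaults(self, params):
        assert (params.I1, params.I2) == (3.1, 0.45)
        assert (params.tau0, params.tau2) == (2857.0, 10.0)
        assert params.gamma_filter == 0.01
        assert params.x_threshold == -2.05

    @pytest.mark.parametrize("bad", [dict(tau0=0), dict(tau2=-1),
                                     dict(gamma_filter=0)])
    def test_rejects_nonpositive_timescales(self, bad):
        with pytest.raises(ParameterError):
            ModelParams(**bad)


class TestBranchFunctions:
    @pytest.mark.parametrize("x1,x2,z,expected", [
        (-1.0, 0.0, 0.0, -4.0),        # cubic branch
        (0.0, 5.0, 7.0, 0.0),          # boundary: multiplied by x1 = 0
        (1.0, 0.5, 4.0, 0.5),          # paraboloid branch
    ])
    def test_f1(self, x1, x2, z, expected):
        assert f1(x1, x2, z) == pytest.approx(expected)

    @pytest.mark.parametrize("x1,x2,expected", [
        (-1.0, 5.0, 0.0),
        (0.0, -0.25, 0.0),
        (0.0, 0.75, 6.0),
    ])
    def test_f2(self, x1, x2, expected):
        assert f2(x1, x2) == pytest.approx(expected)

    def test_f2_branch_convention_switch(self):
        # condition on x2 instead of x1
        assert f2(-1.0, 0.0, branch="x2") == pytest.approx(6.0 * 0.25)
        assert f2(1.0, -0.5, branch="x2") == 0.0

    @pytest.mark.parametrize("args", [(np.nan, 0, 0), (0, np.inf, 0)])
    def test_f1_rejects_nonfinite(self, args):
        with pytest.raises(DomainError):
            f1(*args)

    def test_f2_rejects_nonfinite(self):
        with pytest.raises(DomainError):
            f2(np.nan, 0.0)


class TestDerivatives:
    def test_zero_state(self, params):
        d = derivatives(EpileptorState(0, 0, 0, 0, 0, 0), params, x0=0.0)
        assert d[1] == pytest.approx(1.0)  # dy1 = 1 - 0 - 0

    def test_filter_steady_state(self, params):
        # dg = 0 exactly when g = x1 / gamma
        c = 0.7
        st = EpileptorState(c, 0, 0, 0, 0, c / params.gamma_filter)
        assert derivatives(st, params, x0=0.0)[5] == pytest.approx(0.0, abs=1e-12)

    def test_vanishes_at_fixed_point(self, params):
        # independent oracle: multivariate root of the RHS at x0 = -3
        def rhs(v):
            return derivatives(EpileptorState(*v), params, x0=-3.0)

        sol = optimize.root(rhs, [-1.8, -15.0, -4.0, -1.0, 0.0, -180.0],
                            tol=1e-12)
        assert sol.success
        d = derivatives(EpileptorState(*sol.x), params, x0=-3.0)
        assert np.max(np.abs(d)) < 1e-8

    def test_coupling_sign_conventions(self, params):
        st = EpileptorState(*DEFAULT_INIT)
        up = derivatives(st, params, x0=-2.0, coupling=1.0)
        down = derivatives(st, params, x0=-2.0, coupling=1.0,
                           coupling_convention="printed")
        base = derivatives(st, params, x0=-2.0)
        assert up[2] - base[2] == pytest.approx(1.0 / params.tau0)
        assert down[2] - base[2] == pytest.approx(-1.0 / params.tau0)


class TestIntegrate:
    def test_fourth_order_convergence(self, params):
        # global endpoint error over a smooth relaxation segment shrinks
        # ~16x per halving of dt
        ref = integrate(params, -2.5, duration=10, dt=0.003125).states[-1]
        e_coarse = np.linalg.norm(
            integrate(params, -2.5, duration=10, dt=0.025).states[-1] - ref)
        e_fine = np.linalg.norm(
            integrate(params, -2.5, duration=10, dt=0.0125).states[-1] - ref)
        assert 10 < e_coarse / e_fine < 30

    def test_filter_state_matches_exponential_quadrature(self, params):
        # g must equal the trapezoid quadrature of the exponential-kernel
        # integral of x1 to O(dt^2)
        errs = {}
        for dt in (0.1, 0.05):
            traj = integrate(params, -1.6, duration=200, dt=dt)
            g, x1, t = traj.var("g"), traj.x1, traj.times
            err = 0.0
            for k in (len(t) // 2, len(t) - 1):
                kern = np.exp(-params.gamma_filter * (t[k] - t[: k + 1]))
                quad = np.trapezoid(kern * x1[: k + 1], dx=dt)
                err = max(err, abs(g[k] - quad))
            errs[dt] = err
            assert err < 0.5 * dt ** 2
        assert 2.5 < errs[0.1] / errs[0.05] < 8  # ~4x per halving

    def test_deterministic_bitwise(self, params):
        a = integrate(params, -1.8, duration=500)
        b = integrate(params, -1.8, duration=500)
        assert np.array_equal(a.states, b.states)

    def test_blowup_guard_reports_step(self, params):
        bad = EpileptorState(1e5, 0, 0, 0, 0, 0)
        with pytest.raises(IntegrationBlowupError) as exc:
            integrate(params, -1.6, init=bad, duration=100)
        assert exc.value.step >= 1

    @pytest.mark.parametrize("kwargs", [dict(dt=0), dict(dt=-0.1),
                                        dict(duration=0.01, dt=0.05)])
    def test_rejects_bad_steps(self, params, kwargs):
        with pytest.raises(ParameterError):
            integrate(params, -1.6, **kwargs)


class TestSleSignal:
    def test_conventions(self, constant_traj):
        # constant x1 = -1.6, x2 = -0.6
        summed = sle_signal(constant_traj)
        inverted = sle_signal(constant_traj, "inverted")
        assert np.allclose(summed, -2.2)
        assert np.allclose(inverted, 1.0)

    def test_unknown_convention(self, constant_traj):
        with pytest.raises(ParameterError):
            sle_signal(constant_traj, "upside-down")


class TestClassifyRegime:
    def test_seizing_node_is_oscillatory(self, oscillatory_traj):
        assert classify_regime(oscillatory_traj) == "oscillatory"

    def test_subthreshold_node_is_quiescent(self, quiescent_traj):
        assert classify_regime(quiescent_traj) == "quiescent"

    def test_constant_trajectory_is_quiescent(self, constant_traj):
        assert classify_regime(constant_traj) == "quiescent"

    def test_too_short_raises(self, constant_traj):
        short = Trajectory(times=constant_traj.times[:5],
                           states=constant_traj.states[:5], dt=1.0)
        with pytest.raises(InsufficientDataError):
            classify_regime(short)


class TestFindThreshold:
    def test_recovers_critical_excitability(self, params):
        thr = find_threshold(params, -2.5, -1.6, tol=0.01)
        assert -2.10 <= thr <= -2.00

    def test_bisection_contract(self, params):
        tol = 0.02
        thr = find_threshold(params, -2.5, -1.6, tol=tol)
        below = integrate(params, thr - tol, record_every=10)
        above = integrate(params, thr + tol, record_every=10)
        assert classify_regime(below) == "quiescent"
        assert classify_regime(above) == "oscillatory"

    def test_refinement_self_consistency(self, params):
        coarse = find_threshold(params, -2.5, -1.6, tol=0.02)
        fine = find_threshold(params, -2.5, -1.6, tol=0.005)
        assert abs(coarse - fine) < 0.02

    def test_bad_bracket(self, params):
        with pytest.raises(BracketError):
            find_threshold(params, -1.8, -1.6, tol=0.01,
                           duration=2 * params.tau0)


class TestTrajectory:
    def test_rejects_nonuniform_times(self):
        with pytest.raises(ParameterError):
            Trajectory(times=np.array([0.0, 1.0, 3.0]),
                       states=np.zeros((3, 6)), dt=1.0)

    def test_rejects_single_sample(self):
        with pytest.raises(ParameterError):
            Trajectory(times=np.array([0.0]), states=np.zeros((1, 6)), dt=1.0)
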