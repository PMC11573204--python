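"""Agent model: plant, LQR gains, control law, Kalman fusion, inversion."""

import numpy as np
import pytest

from hapticdyad.agent_model import (
    AgentState,
    ControllerGains,
    CostWeights,
    FusionParams,
    PlantParams,
    control,
    infer_partner_target,
    kalman_update,
    lqr_gains,
    step_dynamics,
)
from hapticdyad.behaviour_metrics import rmse
from hapticdyad.coupling import CouplingSpec
from hapticdyad.protocol import AgentConfig, run_trial


class TestStepDynamics:
    def test_rest_is_fixed_point(self):
        s = step_dynamics(AgentState(), 0.0, 0.0)
        assert (s.q, s.qd) == (0.0, 0.0)

    def test_torque_maps_to_velocity(self):
        s = step_dynamics(AgentState(), 0.001, 0.001)
        assert s.q == 0.0
        assert s.qd == pytest.approx(0.01)

    def test_pure_drift(self):
        s = step_dynamics(AgentState(q=0.1, qd=0.2), 0.0, 0.0)
        assert s.q == pytest.approx(0.102)
        assert s.qd == pytest.approx(0.2)


class TestLqrGains:
    def test_infinite_effort_penalty_kills_gains(self):
        g = lqr_gains(weights=CostWeights(1.0, 0.0, 1e12))
        assert abs(g.lp) < 1e-4 and abs(g.lv) < 1e-4

    def test_matches_value_iteration_oracle(self):
        # brute-force Riccati recursion as independent oracle
        plant = PlantParams()
        w = CostWeights()
        A, B = plant.A, plant.B.reshape(2, 1)
        Q = np.diag([w.w_p, w.w_v])
        R = np.array([[w.r]])
        P = Q.copy()
        for _ in range(100_000):
            K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
            Pn = Q + A.T @ P @ (A - B @ K)
            if np.max(np.abs(Pn - P)) < 1e-15:
                P = Pn
                break
            P = Pn
        K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A).ravel()
        g = lqr_gains(plant, w)
        assert g.lp == pytest.approx(K[0], rel=1e-8)
        assert g.lv == pytest.approx(K[1], rel=1e-8)

    def test_closed_loop_is_stable(self):
        plant = PlantParams()
        g = lqr_gains(plant)
        Acl = plant.A - plant.B.reshape(2, 1) @ np.array([[g.lp, g.lv]])
        assert np.max(np.abs(np.linalg.eigvals(Acl))) < 1.0


class TestControl:
    def test_zero_error_zero_torque(self):
        s = AgentState(q=0.2, qd=0.1, xhat=np.array([0.2, 0.1]))
        assert control(s, ControllerGains(2.0, 0.05)) == 0.0

    def test_position_error_term(self):
        s = AgentState(q=0.1, qd=0.0, xhat=np.array([0.0, 0.0]))
        assert control(s, ControllerGains(2.0, 0.05)) == pytest.approx(-0.2)

    def test_velocity_error_term(self):
        s = AgentState(q=0.0, qd=1.0, xhat=np.array([0.0, 0.0]))
        assert control(s, ControllerGains(2.0, 0.05)) == pytest.approx(-0.05)

    def test_printed_sign_variant_flips_velocity_term(self):
        s = AgentState(q=0.0, qd=1.0, xhat=np.array([0.0, 0.0]))
        assert control(s, ControllerGains(2.0, 0.05), stabilising=False) \
            == pytest.approx(0.05)


class TestKalmanUpdate:
    @staticmethod
    def _flat_state():
        # effectively no prior information
        return AgentState(q=0.0, qd=0.0, xhat=np.zeros(2),
                          P=np.diag([1e12, 1e12]))

    def test_equal_variances_fuse_to_mean(self):
        f = FusionParams(sigma_zv=1.0, sigma_ztv=1.0, sigma_zk=0.0,
                         process_accel_sd=1e-6)
        # rows encode target values 1.0 and 3.0 seen from q = 0
        out = kalman_update(self._flat_state(), [-1.0, -3.0], f)
        assert out.xhat[0] == pytest.approx(2.0, rel=1e-6)

    def test_inverse_variance_weighting(self):
        f = FusionParams(sigma_zv=1.0, sigma_ztv=3.0, sigma_zk=0.0,
                         process_accel_sd=1e-6)
        out = kalman_update(self._flat_state(), [-1.0, -3.0], f)
        assert out.xhat[0] == pytest.approx(0.75 * 1.0 + 0.25 * 3.0, rel=1e-6)

    def test_steady_state_variance_below_single_channel(self):
        f = FusionParams(sigma_zv=2.0, sigma_ztv=0.5, sigma_zk=0.0,
                         process_accel_sd=0.01)
        s = AgentState()
        for _ in range(500):
            s = kalman_update(s, [0.0, 0.0], f)
        assert s.P[0, 0] <= min(f.sigma_zv, f.sigma_zh)

    def test_covariance_stays_symmetric_psd(self, rng):
        f = FusionParams(sigma_zv=0.01, sigma_ztv=0.02)
        s = AgentState()
        for _ in range(3000):
            s = kalman_update(s, rng.normal(0, 0.1, 2), f)
            assert np.allclose(s.P, s.P.T)
            assert np.all(np.linalg.eigvalsh(s.P) >= -1e-12)

    def test_nonpositive_variance_rejected(self):
        f = FusionParams(sigma_zv=1.0, sigma_ztv=0.0, sigma_zk=0.0)
        with pytest.raises(ValueError):
            kalman_update(AgentState(), [0.0, 0.0], f)


class TestInferPartnerTarget:
    def test_relaxed_band_gives_zero(self):
        qt, qr, _ = infer_partner_target(
            0.0, 0.0, 0.0, CouplingSpec(), ControllerGains(2.38, 0.11), 0.01)
        assert qr == 0.0 and qt == 0.0

    def test_static_spring_inversion(self):
        qt, qr, _ = infer_partner_target(
            0.172, 0.0, 0.0, CouplingSpec(), ControllerGains(2.38, 0.11), 0.01)
        assert qr == pytest.approx(0.1)

    def test_zero_stiffness_rejected(self):
        # a zero-stiffness band is uninvertible and cannot be constructed
        with pytest.raises(ValueError):
            CouplingSpec(stiffness=0.0)

    def test_inferred_target_beats_visual_only_estimate(self, rng):
        """With a near-perfect partner the torque-derived target estimate
        is closer to the truth than the agent's own visual estimate."""
        var = np.deg2rad(8.0) ** 2
        agent = AgentConfig(sigma_zv=var)
        partner = AgentConfig(sigma_zv=1e-10)
        solo = run_trial(agent, None, seed=11, sample_t0=False)
        dyad = run_trial(agent, partner, CouplingSpec(), seed=11,
                         sample_t0=False)
        n = dyad.filled
        solo_est_rmse = rmse(solo.qhat[0, :n], solo.target[:n])
        dyad_est_rmse = rmse(dyad.qhat[0, :n], dyad.target[:n])
        assert dyad_est_rmse < solo_est_rmse


def test_skill_monotonicity_over_seeded_trials():
    """Noisier vision gives larger solo tracking error on average."""
    v1, v2 = np.deg2rad(3.0) ** 2, np.deg2rad(12.0) ** 2
    r1, r2 = [], []
    for k in range(50):
        a = run_trial(AgentConfig(sigma_zv=v1), None, seed=k)
        b = run_trial(AgentConfig(sigma_zv=v2), None, seed=k)
        r1.append(rmse(a.q[0], a.target))
        r2.append(rmse(b.q[0], b.target))
    assert np.mean(r1) < np.mean(r2)


def test_validation_errors():
    with pytest.raises(ValueError):
        PlantParams(dt=-0.01)
    with pytest.raises(ValueError):
        CostWeights(w_p=0.0)
    with pytest.raises(ValueError):
        ControllerGains(lp=-1.0, lv=0.1)
    with pytest.raises(ValueError):
        FusionParams(sigma_zv=-1.0)
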