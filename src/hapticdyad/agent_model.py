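"""One tracking agent: wrist plant, optimal feedback controller, sensor fusion.

The wrist is a discrete-time double integrator driven by the net torque
(control plus interaction),

    q_{i+1} = A q_i + B (u_i + tau_i),   A = [[1, dt], [0, 1]],
                                         B = [0, dt / I],

with moment of inertia I = 0.002 kg m^2 and dt = 10 ms.  The control law
is linear state feedback on the tracking error relative to the agent's
current estimate of the target,

    u = -Lp (q - qhat*) - Lv (qdot - qdothat*),

with gains solving the infinite-horizon LQR problem for the error
dynamics under a quadratic cost on error and effort.  (The destabilising
sign sometimes quoted for the velocity term is available behind a flag
for completeness; the stabilising form is the default.)

The target estimate qhat* is maintained by a Kalman filter with a
constant-velocity prior.  Its measurement vector combines a visual error
channel and, during interaction, a haptic channel obtained by inverting
the coupling torque into an estimate of the partner's target:

    z = [q - q*;  q - qtildehat*] + [mu; mutilde],

with mu ~ N(0, Szv) the agent's visual noise and the haptic channel
variance Szh = Sztv + Szk (+ Szd under the compensation-as-noise
strategy), i.e. partner visual noise plus band-compliance noise.
Skill is modelled as the magnitude of Szv: noisier vision, larger solo
tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .coupling import CouplingSpec

__all__ = [
    "PlantParams",
    "CostWeights",
    "ControllerGains",
    "FusionParams",
    "AgentState",
    "step_dynamics",
    "lqr_gains",
    "control",
    "kalman_predict",
    "kalman_update",
    "infer_partner_target",
    "process_noise_cov",
    "DEFAULT_WEIGHTS",
    "DEFAULT_PROCESS_ACCEL_SD",
    "DEFAULT_SIGMA_ZK",
]

#: defaults frozen by scripts/calibrate_defaults.py so that a mid-skill
#: solo agent lands at ~2 deg RMS tracking error
DEFAULT_WEIGHTS = (1.0, 0.0, 0.1)        # (w_p, w_v, r)
DEFAULT_PROCESS_ACCEL_SD = 30.0          # rad/s^2, constant-velocity prior
DEFAULT_SIGMA_ZK = 7.6e-3                # rad^2, band-compliance noise (~5 deg SD)


@dataclass(frozen=True)
class PlantParams:
    """Discrete double-integrator wrist plant."""

    dt: float = 0.01       # s
    inertia: float = 0.002  # kg m^2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.inertia <= 0:
            raise ValueError("dt and inertia must be positive")

    @property
    def A(self) -> np.ndarray:
        return np.array([[1.0, self.dt], [0.0, 1.0]])

    @property
    def B(self) -> np.ndarray:
        return np.array([0.0, self.dt / self.inertia])


@dataclass(frozen=True)
class CostWeights:
    """Stage cost ``w_p e^2 + w_v edot^2 + r u^2`` for the LQR design."""

    w_p: float = DEFAULT_WEIGHTS[0]
    w_v: float = DEFAULT_WEIGHTS[1]
    r: float = DEFAULT_WEIGHTS[2]

    def __post_init__(self) -> None:
        if self.w_p <= 0 or self.r <= 0 or self.w_v < 0:
            raise ValueError("require w_p > 0, r > 0, w_v >= 0")


@dataclass(frozen=True)
class ControllerGains:
    """Proportional/derivative feedback gains (Nm/rad, Nm s/rad)."""

    lp: float
    lv: float

    def __post_init__(self) -> None:
        if self.lp <= 0 or self.lv <= 0:
            raise ValueError("gains must be positive")


@dataclass(frozen=True)
class FusionParams:
    """Noise variances of the two measurement channels (rad^2).

    ``sigma_zv``   own visual channel variance.
    ``sigma_ztv``  partner visual variance carried by the haptic channel.
    ``sigma_zk``   band-compliance (inversion residual) variance.
    ``sigma_zd``   delay-attributed variance; nonzero only under the
                   compensation-as-noise strategy.
    ``process_accel_sd``  white-acceleration SD of the constant-velocity
                   target prior, rad/s^2.
    """

    sigma_zv: float
    sigma_ztv: float = 0.0
    sigma_zk: float = DEFAULT_SIGMA_ZK
    sigma_zd: float = 0.0
    process_accel_sd: float = DEFAULT_PROCESS_ACCEL_SD

    def __post_init__(self) -> None:
        for name in ("sigma_zv", "sigma_ztv", "sigma_zk", "sigma_zd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.process_accel_sd <= 0:
            raise ValueError("process_accel_sd must be positive")

    @property
    def sigma_zh(self) -> float:
        """Total haptic channel variance, ``Sztv + Szk + Szd``."""
        return self.sigma_ztv + self.sigma_zk + self.sigma_zd


@dataclass
class AgentState:
    """Plant state plus target estimate and its covariance."""

    q: float = 0.0
    qd: float = 0.0
    xhat: np.ndarray = field(default_factory=lambda: np.zeros(2))
    P: np.ndarray = field(default_factory=lambda: np.diag([1e-4, 1e-2]))

    def copy(self) -> "AgentState":
        return AgentState(self.q, self.qd, self.xhat.copy(), self.P.copy())


def step_dynamics(state: AgentState, u: float, tau: float,
                  plant: PlantParams = PlantParams()) -> AgentState:
    """Advance the plant one step under net torque ``u + tau``.

    Estimator fields are carried over untouched.
    """
    out = state.copy()
    out.q = state.q + plant.dt * state.qd
    out.qd = state.qd + plant.dt * (u + tau) / plant.inertia
    return out


def lqr_gains(plant: PlantParams = PlantParams(),
              weights: CostWeights = CostWeights()) -> ControllerGains:
    """Infinite-horizon discrete LQR gains for the error dynamics.

    Solves the discrete algebraic Riccati equation for (A, B) with
    ``Q = diag(w_p, w_v)`` and ``R = r``, and returns the optimal state
    feedback ``u = -[lp, lv] e``.  By construction the closed loop
    ``A - B [lp, lv]`` is Schur stable; this is asserted.
    """
    A, B = plant.A, plant.B.reshape(2, 1)
    Q = np.diag([weights.w_p, weights.w_v])
    R = np.array([[weights.r]])
    P = scipy.linalg.solve_discrete_are(A, B, Q, R)
    K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A).ravel()
    gains = ControllerGains(lp=float(K[0]), lv=float(K[1]))
    Acl = A - B @ K.reshape(1, 2)
    if np.max(np.abs(np.linalg.eigvals(Acl))) >= 1.0:
        raise RuntimeError("Riccati solution failed to stabilise the plant")
    return gains


def control(state: AgentState, gains: ControllerGains,
            stabilising: bool = True) -> float:
    """Feedback torque toward the current target estimate (Nm).

    With ``stabilising=False`` the velocity term flips sign, reproducing
    the destabilising variant; it exists only for sensitivity checks.
    """
    ep = state.q - state.xhat[0]
    ev = state.qd - state.xhat[1]
    sign = 1.0 if stabilising else -1.0
    return -gains.lp * ep - sign * gains.lv * ev


def process_noise_cov(dt: float, accel_sd: float) -> np.ndarray:
    """Process noise of the constant-velocity target prior.

    White-acceleration model: ``Q = s^2 [[dt^4/4, dt^3/2], [dt^3/2, dt^2]]``.
    """
    s2 = accel_sd ** 2
    return s2 * np.array([[dt ** 4 / 4.0, dt ** 3 / 2.0],
                          [dt ** 3 / 2.0, dt ** 2]])


def kalman_predict(state: AgentState, plant: PlantParams,
                   fusion: FusionParams) -> AgentState:
    """Time update of the target estimate under the constant-velocity prior."""
    out = state.copy()
    F = np.array([[1.0, plant.dt], [0.0, 1.0]])
    out.xhat = F @ state.xhat
    out.P = F @ state.P @ F.T + process_noise_cov(plant.dt, fusion.process_accel_sd)
    out.P = 0.5 * (out.P + out.P.T)
    return out


def kalman_update(state: AgentState, z, fusion: FusionParams,
                  plant: PlantParams = PlantParams(),
                  predict: bool = True) -> AgentState:
    """Measurement update fusing the visual and (optionally) haptic rows.

    ``z`` is the error-coded measurement: a scalar ``q - q* + mu`` in
    solo trials or the pair ``[q - q* + mu, q - qtildehat* + mutilde]``
    during interaction.  Each row is converted into a direct observation
    of the target position, ``y = q - z``, and applied sequentially with
    measurement variances ``(sigma_zv, sigma_zh)``.  The covariance is
    symmetrised after each update to keep it PSD over long runs.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    variances = [fusion.sigma_zv, fusion.sigma_zh][: len(z)]
    if any(v <= 0 for v in variances):
        raise ValueError("measurement variances must be positive")
    out = kalman_predict(state, plant, fusion) if predict else state.copy()
    H = np.array([1.0, 0.0])
    for zi, var in zip(z, variances):
        y = out.q - zi
        S = H @ out.P @ H + var
        K = out.P @ H / S
        out.xhat = out.xhat + K * (y - out.xhat[0])
        out.P = out.P - np.outer(K, H @ out.P)
        out.P = 0.5 * (out.P + out.P.T)
    return out


def infer_partner_target(tau_measured: float,
                         own_q: float,
                         own_qd: float,
                         coupling: CouplingSpec,
                         gains: ControllerGains,
                         dt: float,
                         target_vel: float = 0.0,
                         tau_prev: float | None = None,
                         qdr_smooth_prev: float | None = None,
                         alpha: float = 0.1,
                         ) -> tuple[float, float, float]:
    """Invert the band torque into an estimate of the partner's target.

    Procedure: (1) recover the partner velocity from the torque trend
    (differentiating the spring term gives ``taudot / K = qdot_r - qdot``),
    smoothed by an exponential moving average with factor ``alpha``
    because the raw trend amplifies control jitter; (2) recover the
    partner angle by inverting the spring-damper law; (3) invert the
    partner's assumed tracking controller quasi-statically — the partner
    reaction torque is ``-tau_measured`` and its inertial term is
    negligible at wrist accelerations, so its control is
    ``u_r ~ tau_measured`` and its target estimate

        qtildehat* = q_r + (tau_measured + Lv (qdot_r - target_vel)) / Lp.

    Returns ``(qtildehat*, q_r, qdot_r_smoothed)``.  The residual of
    this inversion is what the band-compliance variance ``Szk`` absorbs
    in the fusion.
    """
    K, D = coupling.stiffness, coupling.damping
    if K <= 0:
        raise ValueError("band inversion requires positive stiffness")
    if tau_prev is None:
        qdr_s = own_qd
    else:
        qdr = own_qd + (tau_measured - tau_prev) / dt / K
        qdr_s = qdr if qdr_smooth_prev is None \
            else alpha * qdr + (1.0 - alpha) * qdr_smooth_prev
    qr = own_q + (tau_measured - D * (qdr_s - own_qd)) / K
    qtilde = qr + (tau_measured + gains.lv * (qdr_s - target_vel)) / gains.lp
    return qtilde, qr, qdr_s
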