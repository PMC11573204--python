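"""Virtual viscoelastic band between the two agents.

The coupling torque follows a spring-damper law on the state difference,
``tau = K (q_r - q) + D (qdot_r - qdot)`` with the medium-stiffness
constants K = 1.72 Nm/rad and D = 0.0286 Nm s/rad.  One side of the
connection can be perturbed either by a pure transmission delay on the
band arguments or by additive white Gaussian torque noise — never both,
mirroring the two experimental groups.

``calibrate_noise_sd`` implements the rule that matches a noise level to
a delay level: the noise SD is set so that three standard deviations
equal the largest torque error the delay could cause,
``3 sigma = K max|q*(t) - q*(t - delta)|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .target_trajectory import TrajectoryParams, max_delay_displacement

__all__ = [
    "STIFFNESS",
    "DAMPING",
    "DELAY_LEVELS",
    "NOISE_LEVELS",
    "CouplingSpec",
    "band_torque",
    "delayed_tap",
    "add_noise",
    "calibrate_noise_sd",
]

STIFFNESS = 1.72    # Nm/rad
DAMPING = 0.0286    # Nm s/rad

#: experimental perturbation levels
DELAY_LEVELS = (0.0, 0.02, 0.06, 0.18, 0.54)          # s
NOISE_LEVELS = (0.0, 0.0075, 0.0225, 0.0667, 0.184)   # Nm (SD)


@dataclass(frozen=True)
class CouplingSpec:
    """Band constants plus the perturbation applied to one side.

    ``delay`` shifts the band arguments seen by the delayed side by a
    fixed lag; ``noise_sd`` adds white Gaussian torque noise instead.
    The two perturbations are mutually exclusive.
    """

    stiffness: float = STIFFNESS
    damping: float = DAMPING
    delay: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if self.damping < 0 or self.delay < 0 or self.noise_sd < 0:
            raise ValueError("damping, delay and noise_sd must be nonnegative")
        if self.delay > 0 and self.noise_sd > 0:
            raise ValueError(
                "delay and torque noise are mutually exclusive perturbations")

    def delay_steps(self, dt: float) -> int:
        """Delay expressed in simulation steps; must be integral."""
        nd = round(self.delay / dt)
        if abs(nd * dt - self.delay) > 1e-9:
            raise ValueError("delay must be an integer multiple of dt")
        return nd


def band_torque(q_r, q, qdot_r, qdot, spec: CouplingSpec = CouplingSpec()):
    """Torque exerted on the agent at angle ``q`` by the band to ``q_r``."""
    return (spec.stiffness * (np.asarray(q_r) - q)
            + spec.damping * (np.asarray(qdot_r) - qdot))


def delayed_tap(history: np.ndarray, delta: float, dt: float) -> np.ndarray:
    """Read a series through a transmission delay.

    ``history[i]`` holds the band argument at step ``i``; the returned
    array holds the value ``delta/dt`` steps earlier.  Before warm-up the
    oldest available sample is held (zero-order hold of the initial
    state), which matches an interaction that starts from rest.
    """
    history = np.asarray(history)
    nd = round(delta / dt)
    if abs(nd * dt - delta) > 1e-9:
        raise ValueError("delta must be an integer multiple of dt")
    if nd == 0:
        return history.copy()
    idx = np.maximum(np.arange(len(history)) - nd, 0)
    return history[idx]


def add_noise(tau, noise_sd: float, rng: np.random.Generator):
    """Perturb a torque with i.i.d. Gaussian noise of SD ``noise_sd`` Nm."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    tau = np.asarray(tau, dtype=float)
    if noise_sd == 0:
        return tau + 0.0
    return tau + rng.normal(0.0, noise_sd, size=tau.shape)


def calibrate_noise_sd(delta: float,
                       traj: TrajectoryParams | None = None,
                       stiffness: float = STIFFNESS,
                       grid_dt: float = 1e-3) -> float:
    """Noise SD (Nm) whose 3-sigma matches the peak delay-induced torque.

    ``sigma = (K / 3) max_t |q*(t) - q*(t - delta)|``.  With the task
    constants this reproduces the experimental ladder
    {7.5, 22.5, 66.7, 184} mNm for delays {20, 60, 180, 540} ms.
    """
    return stiffness / 3.0 * max_delay_displacement(delta, traj, grid_dt)
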