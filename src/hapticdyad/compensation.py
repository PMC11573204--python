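"""The three haptic delay-handling strategies.

When the band torque reaching an agent is delayed by ``delta``, the
partner-target row of the fusion measurement is stale.  The simulated
central controller can:

* ``none`` — ignore the problem: use the delayed row as if current.
  The row then carries a self-motion bias ``q_i - q_{i-delta}`` that
  feeds back through the controller and can destabilise agents that
  weight the haptic channel heavily (low-skill agents).
* ``noise`` — keep the delayed row but treat the channel as noisier,
  inflating the haptic variance by a delay-attributed term ``Szd``
  obtained by simulating the agent's performance with the uncompensated
  delay and converting the resulting error back into an equivalent
  measurement variance.
* ``predict`` — identify the delay and advance the delayed error row to
  the present by forward-integrating the error dynamics with the known
  plant, controller model and visual target sequence (interaction
  torque omitted, which is what makes the prediction imperfect).

At ``delta = 0`` all three strategies are arithmetically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .agent_model import ControllerGains, PlantParams

__all__ = [
    "STRATEGIES",
    "StrategySpec",
    "measurement_no_compensation",
    "measurement_as_noise",
    "predict_error_forward",
    "delay_noise_variance",
]

STRATEGIES = ("none", "noise", "predict")

_CODES = {"none": _engine.STRAT_NONE,
          "noise": _engine.STRAT_NOISE,
          "predict": _engine.STRAT_PREDICT}


@dataclass(frozen=True)
class StrategySpec:
    """Strategy selector for the perturbed agent.

    ``known_delay`` is the delay the strategy assumes, taken equal to
    the true coupling delay (the controller is modelled as having
    identified it).  ``sigma_zd`` is the delay-attributed variance used
    by the ``noise`` strategy, computed upstream from the agent's
    simulated performance under the uncompensated delay.
    """

    kind: str = "none"
    known_delay: float = 0.0
    sigma_zd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.kind!r}")
        if self.known_delay < 0 or self.sigma_zd < 0:
            raise ValueError("known_delay and sigma_zd must be nonnegative")

    @property
    def code(self) -> int:
        return _CODES[self.kind]


def measurement_no_compensation(q_now: float, qstar_now: float,
                                q_delayed: float, qtilde_hat: float,
                                mu: float = 0.0, mutilde: float = 0.0
                                ) -> np.ndarray:
    """Measurement pair with an uncompensated delayed haptic row.

    ``z = [q_i - q*_i + mu,  q_{i-delta} - qtildehat*_i + mutilde]``.
    With ``delta = 0`` (``q_delayed = q_now``) this is the unperturbed
    interaction measurement.
    """
    return np.array([q_now - qstar_now + mu, q_delayed - qtilde_hat + mutilde])


def measurement_as_noise(q_now: float, qstar_now: float,
                         q_delayed: float, qtilde_hat: float,
                         mu: float = 0.0, mutilde: float = 0.0) -> np.ndarray:
    """Same measurement as :func:`measurement_no_compensation`.

    The strategy differs only in the filter's haptic variance,
    ``Szh = Sztv + Szk + Szd``; the row itself is unchanged.
    """
    return measurement_no_compensation(q_now, qstar_now, q_delayed,
                                       qtilde_hat, mu, mutilde)


def predict_error_forward(e_pos: float, e_vel: float,
                          j: int, i: int,
                          pos: np.ndarray, vel: np.ndarray,
                          plant: PlantParams,
                          gains: ControllerGains) -> tuple[float, float]:
    """Advance a delayed error pair from step ``j`` to step ``i``.

    Iterates the error dynamics under the nominal controller and the
    known target sequence, with the interaction torque omitted:
    ``e_{k+1} = A e_k + B u_k + (A t*_k - t*_{k+1})``,
    ``u_k = -lp e_p - lv e_v``.  The advanced position component
    replaces the haptic measurement row.
    """
    if not 0 <= j <= i < len(pos):
        raise ValueError("require 0 <= j <= i within the target series")
    return _engine.advance_error(float(e_pos), float(e_vel), j, i,
                                 np.asarray(pos, float), np.asarray(vel, float),
                                 plant.dt, plant.inertia, gains.lp, gains.lv)


def delay_noise_variance(delta: float, skill_map,
                         rmse_with_delay_deg: float,
                         rmse_baseline_deg: float) -> float:
    """Delay-attributed haptic variance ``Szd`` (rad^2).

    The error observed when the agent runs with the uncompensated delay
    is converted into an equivalent visual-noise variance through the
    error-to-noise map, and the variance already accounted for at zero
    delay is subtracted; the result is clamped at zero (so ``Szd = 0``
    when ``delta = 0``).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta == 0:
        return 0.0
    v = (skill_map.rmse_to_var(rmse_with_delay_deg)
         - skill_map.rmse_to_var(rmse_baseline_deg))
    return float(max(v, 0.0))
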