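"""Multi-sine tracking target.

The reference signal is a product of two incommensurate sines,

    q*(t) = A sin(w1 (t + t0)) sin(w2 (t + t0)),

with amplitude A = 18.5 deg and angular frequencies w1 = 2.031 rad/s and
w2 = 1.093 rad/s over a 30 s trial.  The product of incommensurate sines
is unpredictable enough to prevent memorisation while staying smooth and
band-limited.  Trials start at a random phase offset t0 chosen from the
zeros of q* so that every trial begins on the centre line.

All angles are stored and computed in radians; degrees appear only at
construction (the printed amplitude) and in reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectoryParams",
    "TargetSeries",
    "target_position",
    "target_velocity",
    "sample_start_time",
    "trajectory_zeros",
    "target_series",
    "max_delay_displacement",
]

#: printed task constants
AMPLITUDE_DEG = 18.5
FREQ1 = 2.031  # rad/s
FREQ2 = 1.093  # rad/s
DURATION = 30.0  # s


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the multi-sine target.

    Attributes
    ----------
    amplitude : float
        Peak angle in radians (default: 18.5 deg converted once).
    freq1, freq2 : float
        Angular frequencies of the two sine factors, rad/s.
    duration : float
        Trial length in seconds.
    t0 : float
        Phase-offset start time in seconds, ``0 <= t0 <= duration``.
    """

    amplitude: float = field(default=math.radians(AMPLITUDE_DEG))
    freq1: float = FREQ1
    freq2: float = FREQ2
    duration: float = DURATION
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.t0 <= self.duration:
            raise ValueError("t0 must lie in [0, duration]")
        if self.freq1 <= 0 or self.freq2 <= 0:
            raise ValueError("angular frequencies must be positive")


def target_position(t, params: TrajectoryParams = TrajectoryParams()):
    """Target angle q*(t) in radians.

    Accepts scalars or arrays.  Negative ``t`` (down to ``-duration``) is
    legal because delayed-feedback code evaluates ``q*(t - delta)``.
    """
    tt = np.asarray(t, dtype=float) + params.t0
    return params.amplitude * np.sin(params.freq1 * tt) * np.sin(params.freq2 * tt)


def target_velocity(t, params: TrajectoryParams = TrajectoryParams()):
    """Analytic derivative of :func:`target_position`, rad/s."""
    tt = np.asarray(t, dtype=float) + params.t0
    w1, w2 = params.freq1, params.freq2
    return params.amplitude * (
        w1 * np.cos(w1 * tt) * np.sin(w2 * tt)
        + w2 * np.sin(w1 * tt) * np.cos(w2 * tt)
    )


def trajectory_zeros(params: TrajectoryParams = TrajectoryParams(),
                     tol: float = 1e-9) -> np.ndarray:
    """All zeros of q* in ``[0, duration]``.

    The product vanishes where either sine factor does, i.e. at every
    ``k pi / w1`` and ``k pi / w2`` inside the window.  The two ladders are
    merged and de-duplicated within ``tol`` seconds.
    """
    zs = []
    for w in (params.freq1, params.freq2):
        kmax = int(math.floor(w * params.duration / math.pi + tol))
        zs.extend(k * math.pi / w for k in range(kmax + 1))
    zs.sort()
    out = [zs[0]]
    for z in zs[1:]:
        if z - out[-1] > tol:
            out.append(z)
    return np.asarray(out)


def sample_start_time(rng: np.random.Generator,
                      params: TrajectoryParams = TrajectoryParams()) -> float:
    """Draw a start time t0 uniformly from the zero set of the target.

    Starting every trial at a zero of q* keeps the initial tracking error
    null regardless of the random phase.
    """
    zeros = trajectory_zeros(params)
    return float(rng.choice(zeros))


@dataclass(frozen=True)
class TargetSeries:
    """A sampled target trajectory (positions and analytic velocities)."""

    t: np.ndarray
    position: np.ndarray
    velocity: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def target_series(params: TrajectoryParams = TrajectoryParams(),
                  dt: float = 0.01) -> TargetSeries:
    """Sample the target on a uniform grid including both endpoints.

    Velocities are analytic, not finite differences, so downstream code
    (forward prediction, SPARC on target velocity) sees no O(dt) bias.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = round(params.duration / dt)
    if abs(n * dt - params.duration) > 1e-9:
        raise ValueError("dt must divide duration")
    t = np.arange(n + 1) * dt
    return TargetSeries(t, target_position(t, params), target_velocity(t, params))


def max_delay_displacement(delta: float,
                           params: TrajectoryParams | None = None,
                           grid_dt: float = 1e-3) -> float:
    """Largest displacement of the target over a lag ``delta``.

    Returns ``max over t in [delta, duration] of |q*(t) - q*(t - delta)|``
    evaluated on a grid of spacing ``grid_dt`` with t0 = 0.  This is the
    quantity that converts a feedback delay into an equivalent maximum
    torque error through the band stiffness.
    """
    if params is None:
        params = TrajectoryParams()
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta > params.duration:
        raise ValueError("delta exceeds the trial duration")
    if delta == 0:
        return 0.0
    base = TrajectoryParams(amplitude=params.amplitude, freq1=params.freq1,
                            freq2=params.freq2, duration=params.duration, t0=0.0)
    t = np.arange(delta, base.duration + grid_dt / 2, grid_dt)
    disp = target_position(t, base) - target_position(t - delta, base)
    return float(np.max(np.abs(disp)))
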