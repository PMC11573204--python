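"""Synthetic data generators standing in for the raw study data.

The experimental cohort's per-participant skills are only available
graphically, so the simulated cohort draws 20 solo-RMSE targets
log-uniformly over a configurable range (default 1-6 deg) — a documented
stand-in, not a reproduction.  EMG traces are generated from a minimal
two-channel linear muscle model consistent with the torque-calibration
procedure: flexor and extensor torques whose difference is the net
tracking torque and whose overlap is the commanded co-contraction
level, pushed through the inverse calibration with additive Gaussian
noise.  No physiological EMG spectrum is emulated.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behaviour_metrics import EmgCalibration

__all__ = [
    "CohortSpec",
    "DEFAULT_CALIBRATION",
    "draw_cohort",
    "synth_emg",
    "synth_calibration_session",
]

#: ground-truth EMG-to-torque maps used by the synthetic generators
DEFAULT_CALIBRATION = EmgCalibration(
    flexor_slope=2.0, flexor_intercept=0.0,
    extensor_slope=-2.0, extensor_intercept=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: size and solo-skill range in degrees RMSE."""

    n: int = 20
    skill_range_deg: tuple = (1.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs at least two participants")
        lo, hi = self.skill_range_deg
        if not 0 < lo < hi:
            raise ValueError("skill range must be positive and ordered")


def draw_cohort(spec: CohortSpec, skill_map) -> list[tuple[float, float]]:
    """Draw per-participant (solo RMSE target, visual variance) pairs.

    Skills are log-uniform over the configured range — skill spreads
    multiplicatively — and mapped to visual-noise variances through the
    empirical skill map.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.skill_range_deg
    rmses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n))
    return [(float(r), float(skill_map.rmse_to_var(r))) for r in rmses]


def synth_emg(level_nm: float, net_torque, noise_sd: float,
              cal: EmgCalibration, seed) -> tuple[np.ndarray, np.ndarray]:
    """Flexor/extensor EMG with known co-contraction level.

    The calibrated torques satisfy ``tau_f - |tau_e| = net_torque`` and
    ``min(tau_f, |tau_e|) = level_nm`` exactly before noise; Gaussian
    noise of SD ``noise_sd`` (EMG units) is added per channel.
    """
    if level_nm < 0:
        raise ValueError("co-contraction level must be nonnegative")
    net = np.asarray(net_torque, dtype=float)
    rng = np.random.default_rng(seed)
    tau_f = np.clip(net, 0.0, None) + level_nm
    tau_e = -(np.clip(-net, 0.0, None) + level_nm)
    emg_f = (tau_f - cal.flexor_intercept) / cal.flexor_slope
    emg_e = (tau_e - cal.extensor_intercept) / cal.extensor_slope
    if noise_sd > 0:
        emg_f = emg_f + rng.normal(0.0, noise_sd, net.shape)
        emg_e = emg_e + rng.normal(0.0, noise_sd, net.shape)
    return emg_f, emg_e


def synth_calibration_session(cal: EmgCalibration, seed,
                              noise_frac: float = 0.0,
                              fs_hz: float = 100.0,
                              plateau_s: float = 2.0
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emulate the torque-calibration protocol.

    Participants hold flexion torques of {1, 2, 3, 4} Nm and then
    extension torques of the same magnitudes, each for 2 s at 100 Hz
    (rest periods omitted from the fitted samples), giving 8 plateaus
    of 200 samples.  The torque actually produced wobbles around the
    commanded plateau with relative SD ``noise_frac``; the EMG reflects
    the produced torque through the inverse calibration, plus a small
    sensor noise (one fifth of the wobble).  Putting the dominant
    variation on the produced torque keeps the subsequent regression
    essentially attenuation-free, as with a well-instrumented rig.

    Returns ``(emg_flexor, emg_extensor, torque)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(plateau_s * fs_hz))
    torques = [float(v) for v in (1, 2, 3, 4)] + [-float(v) for v in (1, 2, 3, 4)]
    emg_f, emg_e, tau = [], [], []
    for tq in torques:
        produced = np.full(n, tq)
        if noise_frac > 0:
            produced = produced + rng.normal(0.0, noise_frac * abs(tq), n)
        tau.append(produced)
        act_f = np.clip(produced, 0.0, None)
        act_e = np.clip(produced, None, 0.0)
        f = (act_f - cal.flexor_intercept) / cal.flexor_slope
        e = (act_e - cal.extensor_intercept) / cal.extensor_slope
        if noise_frac > 0:
            emg_level = abs(tq / cal.flexor_slope)
            f = f + rng.normal(0.0, noise_frac / 5.0 * emg_level, n)
            e = e + rng.normal(0.0, noise_frac / 5.0 * emg_level, n)
        emg_f.append(f)
        emg_e.append(e)
    return (np.concatenate(emg_f), np.concatenate(emg_e), np.concatenate(tau))
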