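"""Behavioural metrics: tracking error, smoothness, lag, co-contraction.

Four per-trial measures summarise tracking behaviour:

* ``rmse`` — root-mean-square tracking error, reported in degrees.
* ``sparc`` — spectral arc length of the speed profile; the negative arc
  length of the normalised magnitude spectrum up to an adaptive cutoff.
  More negative means less smooth.
* ``xcorr_delay`` — the lag maximising the normalised cross-correlation
  between target and response; a proxy for reaction lag.
* ``cocontraction`` — simultaneous flexor/extensor activity,
  ``u(t) = min(tau_f(t), |tau_e(t)|)``, computed from EMG calibrated to
  torque by per-muscle linear regression, then normalised per participant
  to [0, 1] across that participant's trial means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricConfig",
    "EmgCalibration",
    "rmse",
    "sparc",
    "xcorr_delay",
    "fit_emg_calibration",
    "emg_to_torque",
    "cocontraction",
    "normalise_cocontraction",
]


@dataclass(frozen=True)
class MetricConfig:
    """Tunables of the spectral and correlation metrics.

    SPARC parameters follow the published defaults of the metric
    (10 Hz cutoff, 0.05 amplitude threshold, zero-padding level 4).
    """

    sparc_cutoff_hz: float = 10.0
    sparc_amp_threshold: float = 0.05
    sparc_pad_level: int = 4
    xcorr_max_lag_s: float = 2.0
    fs_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.sparc_cutoff_hz <= 0 or self.fs_hz <= 0:
            raise ValueError("frequencies must be positive")
        if not 0.0 < self.sparc_amp_threshold < 1.0:
            raise ValueError("amplitude threshold must lie in (0, 1)")
        if self.xcorr_max_lag_s <= 0:
            raise ValueError("max lag must be positive")


@dataclass(frozen=True)
class EmgCalibration:
    """Per-muscle linear EMG-to-torque maps.

    Sign convention: flexor torque is nonnegative (``flexor_slope > 0``),
    extensor torque nonpositive (``extensor_slope < 0``), both as a
    function of nonnegative EMG activity.
    """

    flexor_slope: float
    flexor_intercept: float
    extensor_slope: float
    extensor_intercept: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.flexor_slope <= 0:
            raise ValueError("flexor slope must be positive")
        if self.extensor_slope >= 0:
            raise ValueError("extensor slope must be negative")


def rmse(response, target) -> float:
    """RMS tracking error in degrees between two angle series (rad)."""
    response = np.asarray(response, dtype=float)
    target = np.asarray(target, dtype=float)
    if response.shape != target.shape:
        raise ValueError("response and target must have equal length")
    return math.degrees(float(np.sqrt(np.mean((response - target) ** 2))))


def sparc(speed, cfg: MetricConfig = MetricConfig()) -> float:
    """Spectral arc length of a speed profile (dimensionless, <= 0).

    The magnitude spectrum of the zero-padded speed signal is normalised
    to unit peak; the arc length of the curve (f / f_range, V(f)) is
    accumulated between the first and last frequency (below the fixed
    cutoff) at which the normalised magnitude exceeds the amplitude
    threshold, and negated.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 2:
        raise ValueError("speed series too short")
    if not np.any(speed != 0.0):
        raise ValueError("SPARC is undefined for an all-zero speed profile")
    nfft = int(2 ** (math.ceil(math.log2(speed.size)) + cfg.sparc_pad_level))
    freqs = np.arange(nfft) * (cfg.fs_hz / nfft)
    mag = np.abs(np.fft.fft(speed, nfft))
    mag = mag / np.max(mag)
    sel = freqs <= cfg.sparc_cutoff_hz
    f_sel, m_sel = freqs[sel], mag[sel]
    above = np.nonzero(m_sel >= cfg.sparc_amp_threshold)[0]
    f_sel = f_sel[above[0]: above[-1] + 1]
    m_sel = m_sel[above[0]: above[-1] + 1]
    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    return -float(np.sum(np.sqrt(df ** 2 + np.diff(m_sel) ** 2)))


def xcorr_delay(target, response, cfg: MetricConfig = MetricConfig()) -> float:
    """Lag (s) maximising the normalised target/response cross-correlation.

    Positive values mean the response lags the target.  Both series are
    z-scored; the search is limited to ``|lag| <= xcorr_max_lag_s`` and
    ties are broken toward the smallest absolute lag.
    """
    target = np.asarray(target, dtype=float)
    response = np.asarray(response, dtype=float)
    if target.shape != response.shape:
        raise ValueError("series must have equal length")
    if np.ptp(target) == 0 or np.ptp(response) == 0:
        raise ValueError("cross-correlation is undefined for constant series")
    t = (target - target.mean()) / target.std()
    r = (response - response.mean()) / response.std()
    n = len(t)
    max_shift = min(int(round(cfg.xcorr_max_lag_s * cfg.fs_hz)), n - 1)
    full = np.correlate(r, t, mode="full")  # index n-1+k <-> response shifted by k
    lags = np.arange(-max_shift, max_shift + 1)
    vals = full[n - 1 + lags]
    # stable tie-break: among near-equal maxima prefer the smallest |lag|
    best = np.max(vals)
    cand = lags[vals >= best - 1e-12 * abs(best)]
    k = cand[np.argmin(np.abs(cand))]
    return float(k) / cfg.fs_hz


def fit_emg_calibration(emg_flexor, emg_extensor, torque) -> EmgCalibration:
    """Least-squares linear EMG-to-torque maps from a calibration session.

    Flexor samples are those with nonnegative measured torque, extensor
    samples the rest; each muscle gets an ordinary least-squares line
    ``torque = slope * emg + intercept``.
    """
    emg_flexor = np.asarray(emg_flexor, dtype=float)
    emg_extensor = np.asarray(emg_extensor, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if not (len(emg_flexor) == len(emg_extensor) == len(torque)):
        raise ValueError("calibration series must share one length")
    flex = torque >= 0
    ext = ~flex
    if flex.sum() < 2 or ext.sum() < 2:
        raise ValueError("calibration needs samples in both directions")
    resid = []
    coefs = []
    for mask, emg in ((flex, emg_flexor), (ext, emg_extensor)):
        X = np.column_stack([emg[mask], np.ones(mask.sum())])
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError("rank-deficient calibration design")
        beta, *_ = np.linalg.lstsq(X, torque[mask], rcond=None)
        coefs.append(beta)
        resid.append(torque[mask] - X @ beta)
    residual_sd = float(np.std(np.concatenate(resid)))
    return EmgCalibration(
        flexor_slope=float(coefs[0][0]),
        flexor_intercept=float(coefs[0][1]),
        extensor_slope=float(coefs[1][0]),
        extensor_intercept=float(coefs[1][1]),
        residual_sd=residual_sd,
    )


def emg_to_torque(emg_flexor, emg_extensor,
                  cal: EmgCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Apply the calibration, returning ``(tau_f >= 0, tau_e <= 0)``.

    Small sign violations from noisy EMG are clipped to the admissible
    half-lines.
    """
    tau_f = cal.flexor_slope * np.asarray(emg_flexor, float) + cal.flexor_intercept
    tau_e = cal.extensor_slope * np.asarray(emg_extensor, float) + cal.extensor_intercept
    return np.clip(tau_f, 0.0, None), np.clip(tau_e, None, 0.0)


def cocontraction(tau_f, tau_e) -> np.ndarray:
    """Sample-wise co-contraction ``min(tau_f, |tau_e|)`` in Nm.

    ``tau_f`` must be nonnegative and ``tau_e`` nonpositive; violations
    are clipped (they can only arise from noisy calibration output).
    """
    tau_f = np.clip(np.asarray(tau_f, dtype=float), 0.0, None)
    tau_e = np.clip(np.asarray(tau_e, dtype=float), None, 0.0)
    return np.minimum(tau_f, np.abs(tau_e))


def normalise_cocontraction(trial_means) -> np.ndarray:
    """Normalise one participant's trial-mean co-contractions to [0, 1].

    ``u_n = (ubar - ubar_min) / (ubar_max - ubar_min)`` over that
    participant's trials; undefined when all trial means coincide.
    """
    u = np.asarray(trial_means, dtype=float)
    if u.size < 2:
        raise ValueError("need at least two trial means")
    lo, hi = np.min(u), np.max(u)
    if hi == lo:
        raise ValueError("normalisation undefined: all trial means equal")
    return (u - lo) / (hi - lo)
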