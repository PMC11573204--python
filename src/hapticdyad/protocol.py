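"""Trial, block and cohort orchestration.

Reproduces the structure of the tracking study: per participant, six
blocks of ten 30 s trials (seven interaction trials whose metrics are
averaged, three solo washout trials that are simulated but excluded
from block summaries).  Block 0 is solo; blocks 1-5 couple the
participant to a skill-matched partner with an increasing perturbation
level (delay group or torque-noise group).  A cohort is 20 simulated
participants spanning a range of solo skills.

The partner's skill is matched after the solo block through an
empirical error-to-noise map (:func:`build_skill_map`): solo trials are
simulated over a grid of visual-noise variances and the resulting RMS
errors interpolated, giving a monotone bijection between solo RMSE and
visual noise that is also used to attribute delay-induced error to an
equivalent variance (compensation-as-noise strategy).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .agent_model import (
    DEFAULT_PROCESS_ACCEL_SD,
    DEFAULT_SIGMA_ZK,
    ControllerGains,
    CostWeights,
    PlantParams,
    lqr_gains,
    process_noise_cov,
)
from .behaviour_metrics import MetricConfig, cocontraction, rmse, sparc, xcorr_delay
from .compensation import StrategySpec, delay_noise_variance
from .coupling import DELAY_LEVELS, NOISE_LEVELS, CouplingSpec
from .target_trajectory import TrajectoryParams, sample_start_time, target_series

__all__ = [
    "GUARD_RAD",
    "AgentConfig",
    "ProtocolSpec",
    "TrialRecord",
    "SkillMap",
    "run_trial",
    "trial_metrics",
    "build_skill_map",
    "match_partner_skill",
    "delay_noise_for",
    "run_cohort",
]

#: divergence guard on |q|; keeps runaway no-compensation trials
#: representable without floating-point overflow
GUARD_RAD = 10.0


@dataclass(frozen=True)
class AgentConfig:
    """Per-agent configuration: skill (visual noise) and controller cost."""

    sigma_zv: float                      # visual noise variance, rad^2
    weights: CostWeights = field(default_factory=CostWeights)
    sigma_zk: float = DEFAULT_SIGMA_ZK   # band-compliance variance, rad^2
    process_accel_sd: float = DEFAULT_PROCESS_ACCEL_SD
    infer_alpha: float = 0.1             # EMA factor of the torque-trend velocity

    def __post_init__(self) -> None:
        if self.sigma_zv < 0:
            raise ValueError("sigma_zv must be nonnegative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Block/trial structure of one experimental session."""

    trial_duration: float = 30.0
    interaction_trials: int = 7
    washout_trials: int = 3
    delay_levels: tuple = DELAY_LEVELS
    noise_levels: tuple = NOISE_LEVELS
    cohort_size: int = 20


@dataclass
class TrialRecord:
    """Time series of one simulated trial (agent 0 is the participant)."""

    t: np.ndarray
    target: np.ndarray          # rad
    q: np.ndarray               # (2, n) rad
    qd: np.ndarray              # (2, n) rad/s
    u: np.ndarray               # (2, n) Nm, control
    tau: np.ndarray             # (2, n) Nm, applied interaction torque
    band: np.ndarray            # (n,) Nm, unperturbed band torque
    qhat: np.ndarray            # (2, n) rad, target estimates
    filled: int
    diverged: bool
    meta: dict

    def to_frame(self) -> pd.DataFrame:
        n = self.filled
        return pd.DataFrame({
            "time_s": self.t[:n],
            "target_rad": self.target[:n],
            "q_rad": self.q[0, :n],
            "qd_rad_s": self.qd[0, :n],
            "partner_q_rad": self.q[1, :n],
            "partner_qd_rad_s": self.qd[1, :n],
            "u_nm": self.u[0, :n],
            "partner_u_nm": self.u[1, :n],
            "tau_nm": self.tau[0, :n],
            "band_nm": self.band[:n],
            "qhat_rad": self.qhat[0, :n],
        })


@functools.lru_cache(maxsize=None)
def _gains_cached(plant: PlantParams, weights: CostWeights) -> ControllerGains:
    return lqr_gains(plant, weights)


def run_trial(agent: AgentConfig,
              partner: AgentConfig | None,
              coupling: CouplingSpec | None = None,
              strategy: StrategySpec = StrategySpec(),
              traj: TrajectoryParams | None = None,
              seed=0,
              plant: PlantParams = PlantParams(),
              sample_t0: bool = True,
              visual_delay: float = 0.0) -> TrialRecord:
    """Closed-loop co-simulation of one 30 s trial.

    ``partner=None`` gives a solo trial (no coupling torque, no haptic
    channel).  The participant side receives the perturbed torque
    (delayed tap or additive noise); the partner always receives the
    current, noise-free band torque.  Divergent trials are truncated
    and flagged, never raised.
    """
    if coupling is None:
        coupling = CouplingSpec()
    params = traj if traj is not None else TrajectoryParams()
    rng = np.random.default_rng(seed)
    if sample_t0:
        params = replace(params, t0=sample_start_time(rng, params))
    if strategy.kind in ("noise", "predict") and partner is not None:
        if abs(strategy.known_delay - coupling.delay) > 1e-12:
            raise ValueError("strategy.known_delay must equal the coupling delay")

    nd = coupling.delay_steps(plant.dt)
    nd_vis = round(visual_delay / plant.dt)
    if abs(nd_vis * plant.dt - visual_delay) > 1e-9:
        raise ValueError("visual_delay must be an integer multiple of dt")
    n = round(params.duration / plant.dt)
    series = target_series(params, plant.dt)
    pos = np.ascontiguousarray(series.position)
    vel = np.ascontiguousarray(series.velocity)

    mu0 = rng.normal(0.0, 1.0, n) * np.sqrt(agent.sigma_zv)
    mu1 = rng.normal(0.0, 1.0, n)
    eta = rng.normal(0.0, 1.0, n) * coupling.noise_sd

    coupled = partner is not None
    if coupled:
        mu1 *= np.sqrt(partner.sigma_zv)
        rh0 = partner.sigma_zv + agent.sigma_zk
        if strategy.kind == "noise":
            rh0 += strategy.sigma_zd
        rh1 = agent.sigma_zv + partner.sigma_zk
        gains1 = _gains_cached(plant, partner.weights)
    else:
        mu1 *= 0.0
        rh0 = rh1 = 1.0  # unused
        gains1 = _gains_cached(plant, agent.weights)
    gains0 = _gains_cached(plant, agent.weights)

    Q = process_noise_cov(plant.dt, agent.process_accel_sd)

    q_out = np.empty((2, n))
    qd_out = np.empty((2, n))
    u_out = np.empty((2, n))
    tau_out = np.empty((2, n))
    band_out = np.empty(n)
    qhat_out = np.empty((2, n))

    filled, diverged = _engine.run_pair(
        pos, vel, plant.dt, plant.inertia,
        gains0.lp, gains0.lv, gains1.lp, gains1.lv,
        max(agent.sigma_zv, 1e-12), max(partner.sigma_zv, 1e-12) if coupled else 1e-12,
        rh0, rh1,
        Q[0, 0], Q[0, 1], Q[1, 1],
        coupling.stiffness, coupling.damping, nd, nd_vis, coupled, strategy.code,
        mu0, mu1, eta,
        agent.infer_alpha, GUARD_RAD,
        q_out, qd_out, u_out, tau_out, band_out, qhat_out)

    return TrialRecord(
        t=series.t[:n], target=pos[:n], q=q_out, qd=qd_out, u=u_out,
        tau=tau_out, band=band_out, qhat=qhat_out,
        filled=int(filled), diverged=bool(diverged),
        meta={"t0": params.t0, "delay": coupling.delay,
              "noise_sd": coupling.noise_sd, "strategy": strategy.kind,
              "coupled": coupled})


def trial_metrics(rec: TrialRecord,
                  cfg: MetricConfig = MetricConfig()) -> dict:
    """Per-trial behavioural metrics (on the truncated series if divergent)."""
    n = rec.filled
    out = {"diverged": rec.diverged}
    out["rmse_deg"] = rmse(rec.q[0, :n], rec.target[:n])
    speed = np.abs(rec.qd[0, :n])
    try:
        out["sparc"] = sparc(speed, cfg)
    except ValueError:
        out["sparc"] = np.nan
    try:
        out["lag_s"] = xcorr_delay(rec.target[:n], rec.q[0, :n], cfg)
    except ValueError:
        out["lag_s"] = np.nan
    return out


class SkillMap:
    """Monotone empirical map between solo RMSE (deg) and visual variance.

    Interpolation is linear in log-log space; queries outside the
    calibrated range are extrapolated with the boundary slope and
    flagged with a warning.
    """

    def __init__(self, var_grid: np.ndarray, rmse_deg: np.ndarray):
        var_grid = np.asarray(var_grid, float)
        rmse_deg = np.asarray(rmse_deg, float)
        if np.any(np.diff(var_grid) <= 0):
            raise ValueError("var_grid must be strictly increasing")
        if np.any(np.diff(rmse_deg) < 0):
            # enforce monotonicity (sampling noise can produce dips)
            from sklearn.isotonic import IsotonicRegression
            warnings.warn("empirical skill curve not monotone; "
                          "isotonic regression applied")
            iso = IsotonicRegression(increasing=True)
            rmse_deg = iso.fit_transform(np.log(var_grid), rmse_deg)
        # strictly increasing for invertibility
        eps = 1e-9
        rmse_deg = np.maximum.accumulate(rmse_deg + eps * np.arange(len(rmse_deg)))
        self.var_grid = var_grid
        self.rmse_deg = rmse_deg
        self._lv = np.log(var_grid)
        self._lr = np.log(rmse_deg)

    @staticmethod
    def _interp(x, xp, fp, label):
        x = np.log(np.asarray(x, float))
        if np.any(x < xp[0]) or np.any(x > xp[-1]):
            warnings.warn(f"skill map query outside calibrated {label} range; "
                          "extrapolating")
        lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.interp(x, xp, fp)
        y = np.where(x < xp[0], fp[0] + (x - xp[0]) * lo_slope, y)
        y = np.where(x > xp[-1], fp[-1] + (x - xp[-1]) * hi_slope, y)
        return np.exp(y)

    def var_to_rmse(self, var):
        """Expected solo RMSE (deg) at visual variance ``var`` (rad^2)."""
        out = self._interp(var, self._lv, self._lr, "variance")
        return float(out) if np.isscalar(var) else out

    def rmse_to_var(self, rmse_deg):
        """Visual variance (rad^2) producing solo RMSE ``rmse_deg``."""
        out = self._interp(rmse_deg, self._lr, self._lv, "RMSE")
        return float(out) if np.isscalar(rmse_deg) else out


#: default calibration grid: visual noise SD from ~0.1 deg to ~60 deg
DEFAULT_VAR_GRID = np.geomspace(2e-6, 1.0, 13)


def build_skill_map(var_grid=None,
                    trials_per_point: int = 4,
                    base_seed: int = 12345,
                    plant: PlantParams = PlantParams(),
                    weights: CostWeights = CostWeights()) -> SkillMap:
    """Calibrate the error-to-noise map by simulating solo trials.

    For each visual variance on the grid the mean solo RMSE over
    ``trials_per_point`` seeded trials is recorded; the resulting curve
    is monotone (isotonic-corrected if sampling noise dents it).
    """
    if var_grid is None:
        var_grid = DEFAULT_VAR_GRID
    var_grid = np.asarray(var_grid, float)
    means = []
    for gi, var in enumerate(var_grid):
        agent = AgentConfig(sigma_zv=float(var), weights=weights)
        vals = []
        for k in range(trials_per_point):
            rec = run_trial(agent, None, seed=np.random.SeedSequence(
                (base_seed, 101, gi, k)), plant=plant)
            vals.append(rmse(rec.q[0, :rec.filled], rec.target[:rec.filled]))
        means.append(np.mean(vals))
    return SkillMap(var_grid, np.asarray(means))


def match_partner_skill(solo_rmse_deg: float, skill_map: SkillMap) -> float:
    """Partner visual variance whose expected solo RMSE matches the observed one."""
    return float(skill_map.rmse_to_var(solo_rmse_deg))


def delay_noise_for(agent: AgentConfig, partner: AgentConfig,
                    delta: float, skill_map: SkillMap,
                    base_seed: int = 0, pid: int = 0,
                    n_trials: int = 2,
                    plant: PlantParams = PlantParams()) -> float:
    """Delay-attributed variance ``Szd`` for one agent at one delay level.

    Simulates the agent's performance with the uncompensated delayed
    haptic signal (and at zero delay as baseline) and converts the
    error excess into an equivalent measurement variance through the
    error-to-noise map, so that a delay which degrades tracking more is
    attributed a proportionally larger haptic noise.
    """
    if delta == 0:
        return 0.0

    def mean_rmse(d, tag):
        vals = []
        for k in range(n_trials):
            rec = run_trial(agent, partner, CouplingSpec(delay=d),
                            StrategySpec("none"),
                            seed=np.random.SeedSequence((base_seed, 202, pid, tag, k)),
                            plant=plant)
            vals.append(rmse(rec.q[0, :rec.filled], rec.target[:rec.filled]))
        return float(np.mean(vals))

    r_delay = mean_rmse(delta, round(delta * 1000))
    r_base = mean_rmse(0.0, 0)
    return delay_noise_variance(delta, skill_map, r_delay, r_base)


def run_cohort(participants,
               skill_map: SkillMap,
               strategies=("none", "noise", "predict"),
               group: str = "delay",
               base_seed: int = 0,
               spec: ProtocolSpec = ProtocolSpec(),
               plant: PlantParams = PlantParams(),
               weights: CostWeights = CostWeights(),
               simulate_washouts: bool = True,
               emg_level_nm: float = 0.1) -> pd.DataFrame:
    """Simulate the full protocol for a cohort and summarise per block.

    ``participants`` is a sequence of ``(target_rmse_deg, sigma_zv)``
    pairs (see :func:`hapticdyad.synthetic_cohort.draw_cohort`).  Trial
    seeds depend on (base_seed, participant, block, trial) but not on
    the strategy, so at zero perturbation the three strategies produce
    bitwise-identical trials.  Returns a long table with one row per
    participant x block x strategy carrying the mean metrics of the
    seven interaction trials (washouts simulated, excluded).
    """
    if group not in ("delay", "noise"):
        raise ValueError("group must be 'delay' or 'noise'")
    levels = spec.delay_levels if group == "delay" else spec.noise_levels
    rows = []
    from .synthetic_cohort import DEFAULT_CALIBRATION

    for pid, (rmse_target, var) in enumerate(participants):
        agent = AgentConfig(sigma_zv=float(var), weights=weights)

        # --- solo block (block 0), shared by all strategies ----------
        solo_metrics = []
        for k in range(spec.interaction_trials + spec.washout_trials):
            rec = run_trial(agent, None,
                            seed=np.random.SeedSequence((base_seed, pid, 0, k)),
                            plant=plant)
            m = trial_metrics(rec)
            m["cocontraction_nm"] = _trial_cocontraction(
                rec, emg_level_nm, DEFAULT_CALIBRATION,
                np.random.SeedSequence((base_seed, pid, 0, k, 7)))
            solo_metrics.append(m)
        solo_block = solo_metrics[: spec.interaction_trials]
        solo_rmse = float(np.mean([m["rmse_deg"] for m in solo_block]))
        partner = AgentConfig(sigma_zv=match_partner_skill(solo_rmse, skill_map),
                              weights=weights)

        # delay-attributed variances for the as-noise strategy
        szd = {}
        if "noise" in strategies and group == "delay":
            for lev in levels:
                szd[lev] = delay_noise_for(agent, partner, lev, skill_map,
                                           base_seed=base_seed, pid=pid,
                                           plant=plant)

        for strat in strategies:
            rows.append(_block_row(pid, rmse_target, strat, group, 0, 0.0,
                                   solo_block))
            for b, lev in enumerate(levels, start=1):
                if group == "delay":
                    coup = CouplingSpec(delay=lev)
                    strat_spec = StrategySpec(strat, known_delay=lev,
                                              sigma_zd=szd.get(lev, 0.0))
                else:
                    coup = CouplingSpec(noise_sd=lev)
                    strat_spec = StrategySpec(strat, known_delay=0.0)
                block_metrics = []
                for k in range(spec.interaction_trials):
                    rec = run_trial(agent, partner, coup, strat_spec,
                                    seed=np.random.SeedSequence(
                                        (base_seed, pid, b, k)),
                                    plant=plant)
                    m = trial_metrics(rec)
                    m["cocontraction_nm"] = _trial_cocontraction(
                        rec, emg_level_nm, DEFAULT_CALIBRATION,
                        np.random.SeedSequence((base_seed, pid, b, k, 7)))
                    block_metrics.append(m)
                if simulate_washouts:
                    for k in range(spec.washout_trials):
                        run_trial(agent, None,
                                  seed=np.random.SeedSequence(
                                      (base_seed, pid, b, 100 + k)),
                                  plant=plant)
                rows.append(_block_row(pid, rmse_target, strat, group, b,
                                       lev, block_metrics))
    return pd.DataFrame(rows)


def _trial_cocontraction(rec: TrialRecord, level_nm: float, cal, seed) -> float:
    """Mean co-contraction of synthetic EMG driven by the trial's torque."""
    from .behaviour_metrics import emg_to_torque
    from .synthetic_cohort import synth_emg
    net = rec.u[0, :rec.filled]
    emg_f, emg_e = synth_emg(level_nm, net, 0.02, cal, seed)
    tf, te = emg_to_torque(emg_f, emg_e, cal)
    return float(np.mean(cocontraction(tf, te)))


def _block_row(pid, rmse_target, strat, group, block, level, metrics) -> dict:
    return {
        "participant": pid,
        "skill_rmse_target_deg": rmse_target,
        "strategy": strat,
        "group": group,
        "block": block,
        "level": level,
        "rmse_deg": float(np.mean([m["rmse_deg"] for m in metrics])),
        "sparc": float(np.nanmean([m["sparc"] for m in metrics])),
        "lag_s": float(np.nanmean([m["lag_s"] for m in metrics])),
        "cocontraction_nm": float(np.mean([m["cocontraction_nm"] for m in metrics])),
        "diverged_frac": float(np.mean([m["diverged"] for m in metrics])),
        "n_trials": len(metrics),
    }
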