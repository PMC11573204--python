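# hapticdyad

Simulation and analysis of **haptic communication between two tracking
agents** coupled by a virtual viscoelastic band, for studying how a
sensorimotor controller can cope with **delayed** or **noisy** haptic
feedback.

Two agents track the same multi-sine target
`q*(t) = 18.5° · sin(2.031 (t+t0)) · sin(1.093 (t+t0))` with a wrist
modelled as a discrete double integrator
(`q_{i+1} = A q_i + B (u_i + τ_i)`, I = 0.002 kg·m², dt = 10 ms), an
LQR feedback law `u = −Lp (q − q̂*) − Lv (q̇ − q̇̂*)`, and a Kalman
filter that fuses a visual channel with a haptic channel inferred by
inverting the coupling torque
`τ = 1.72 (q_r − q) + 0.0286 (q̇_r − q̇)` Nm. Skill is visual-noise
magnitude; the robot partner is skill-matched through an empirical
error-to-noise map. The band can be perturbed by a transmission delay
δ ∈ {0, 20, 60, 180, 540} ms or by Gaussian torque noise calibrated so
that 3σ equals the worst torque error the matched delay could cause
(σ ∈ {7.5, 22.5, 66.7, 184} mNm).

Three candidate strategies for the delayed haptic channel are
implemented and compared on a synthetic 20-participant cohort:

* **none** — use the stale channel as if current (self-motion bias,
  destabilises low-skill agents at long delays);
* **noise** — keep the channel but inflate its assumed variance by a
  delay-attributed term `Σ_zd`;
* **predict** — advance the delayed error by forward-integrating the
  known dynamics and target sequence (torque unmeasured, hence
  imperfect).

Behavioural metrics (RMSE, SPARC smoothness, cross-correlation lag,
EMG co-contraction with per-participant normalisation) and the
statistical stage (Friedman, paired Wilcoxon signed-rank with Hommel
adjustment, two-sided variance F-test) are included, plus synthetic-EMG
generators for the co-contraction pipeline. See `docs/methods.md` for
the model, parameter rationale and limitations.

## Worked example

```python
import numpy as np
from hapticdyad.coupling import CouplingSpec, calibrate_noise_sd
from hapticdyad.compensation import StrategySpec
from hapticdyad.protocol import AgentConfig, run_trial, trial_metrics

print([round(calibrate_noise_sd(d) * 1e3, 1) for d in (0.02, 0.06, 0.18, 0.54)])

agent = AgentConfig(sigma_zv=np.deg2rad(7.0) ** 2)   # mid-skill
partner = AgentConfig(sigma_zv=np.deg2rad(7.0) ** 2)  # matched robot
for name, rec in [
    ("solo", run_trial(agent, None, seed=0)),
    ("dyad delta=0", run_trial(agent, partner, CouplingSpec(),
                               StrategySpec("none"), seed=0)),
    ("dyad 540ms none", run_trial(agent, partner, CouplingSpec(delay=0.54),
                                  StrategySpec("none", known_delay=0.54),
                                  seed=0)),
    ("dyad 540ms predict", run_trial(agent, partner, CouplingSpec(delay=0.54),
                                     StrategySpec("predict", known_delay=0.54),
                                     seed=0)),
]:
    m = trial_metrics(rec)
    print(f"{name:20s} rmse {m['rmse_deg']:.2f} deg  sparc {m['sparc']:.2f}")
```

prints

```
[7.5, 22.5, 66.8, 184.2]
solo                 rmse 3.14 deg  sparc -9.19
dyad delta=0         rmse 2.77 deg  sparc -9.01
dyad 540ms none      rmse 4.12 deg  sparc -9.54
dyad 540ms predict   rmse 2.92 deg  sparc -9.27
```

The first line is the delay-matched torque-noise ladder in mNm. The
trial metrics show the core phenomenology: connecting the matched
partner improves tracking (3.14° → 2.77°); a 540 ms delay without
compensation makes the dyad worse than solo (4.12°); identifying the
delay and predicting through it recovers most of the loss (2.92°).
SPARC is the spectral-arc-length smoothness (more negative = jerkier).

The same from the shell:

```
dyad calibrate-noise
dyad trial --strategy predict --delay 0.54 --skill-deg 7 --out trial.csv
dyad metrics --in trial.csv
dyad cohort --group delay --seed 1 --out cohort.csv
dyad stats --in cohort.csv --out report.json
```

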