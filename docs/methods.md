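# Methods

## Task and model overview

Two agents track the multi-sine target
`q*(t) = A sin(w1 (t+t0)) sin(w2 (t+t0))` (A = 18.5°, w1 = 2.031 rad/s,
w2 = 1.093 rad/s, 30 s trials at 100 Hz) with their wrist while a
virtual spring–damper band (K = 1.72 Nm/rad, D = 0.0286 Nm·s/rad)
couples them. Each trial starts at a `t0` drawn uniformly from the 30
zeros of the target in [0, 30] s, so every trial begins on the centre
line. One side of the band can be perturbed by a transmission delay
δ ∈ {0, 20, 60, 180, 540} ms on the band arguments, or by additive
white torque noise whose SD is calibrated so that 3σ equals the largest
torque error the matched delay could cause,
`σ = (K/3)·max_t |q*(t) − q*(t−δ)|`; with the task constants this gives
{7.5, 22.5, 66.7, 184} mNm. Delay and noise are mutually exclusive, and
the partner always receives the current, noise-free band torque.

Each agent is an LQG-style loop:

* **Plant** — discrete double integrator, `q_{i+1} = A q_i + B (u_i + τ_i)`
  with `A = [[1, dt], [0, 1]]`, `B = [0, dt/I]`, I = 0.002 kg·m²,
  dt = 10 ms.
* **Controller** — `u = −Lp (q − q̂*) − Lv (q̇ − q̇̂*)`, the
  infinite-horizon LQR solution for the error dynamics under the stage
  cost `w_p e² + w_v ė² + r u²`. A destabilising velocity-term sign
  sometimes quoted for this law is available behind a flag for
  sensitivity checks; the stabilising form is the default.
* **Estimator** — a Kalman filter over the target state
  `[q*, q̇*]` with a constant-velocity prior (white-acceleration process
  noise) and up to two position measurements per step, both coded as
  errors relative to the agent's own angle: a visual row
  `z_v = q − q* + μ`, `μ ~ N(0, Σ_zv)`, and during interaction a haptic
  row `z_h = q − q̃̂* + μ̃` whose content `q̃̂*` is inferred from the
  coupling torque. The filter's haptic variance is
  `Σ_zh = Σ_z̃v + Σ_zk (+ Σ_zd)`: partner visual noise, band-compliance
  noise, and (under the as-noise strategy only) a delay-attributed term.

Skill is the magnitude of `Σ_zv`: noisier vision produces larger solo
RMSE. The robot partner runs the identical loop; its `Σ_z̃v` is set
after the solo block so that its expected solo error matches the
participant's observed one (skill matching).

## Haptic inversion

The torque is inverted into a partner-target estimate in three steps:
the partner velocity from the smoothed torque trend
(`τ̇/K = q̇_r − q̇`, exponential moving average with factor
`infer_alpha = 0.1`, because the raw finite difference amplifies the
partner's control jitter), the partner angle from the spring–damper
law, and the partner's goal from a quasi-static inversion of its
assumed controller, `q̃̂* = q_r + (τ + Lv(q̇_r − q̇*))/Lp`. The
partner's inertial torque (`I q̈_r ≲ 0.006 Nm`) is negligible against
the band torque and is not reconstructed; its omission, the damping
correction and the smoothing lag are the residuals that the
band-compliance variance `Σ_zk` absorbs.

## Delay strategies

With a transmission delay the torque reflects the band state δ earlier,
so the haptic row pairs the agent's *remembered* state at t−δ with
stale partner information: `z_h = q_{i−δ} − q̃̂*_i`.

* **No compensation** treats that row as current. The filter then
  ingests a self-motion bias `q_i − q_{i−δ}`, a positive feedback that
  grows with the haptic weight. Because `Σ_zk` is a constant, low-skill
  agents (large `Σ_zv`) weight the haptic channel near ½ while skilled
  agents discount it — the delay therefore destabilises the cohort from
  the least skilled end, producing the heavy upper tail at 540 ms.
* **Compensation as noise** uses the same row but inflates the filter's
  haptic variance by `Σ_zd`, obtained per agent and delay by simulating
  the uncompensated delayed interaction, converting the excess RMSE
  into an equivalent measurement variance through the error-to-noise
  map, and clamping at zero (so `Σ_zd = 0` at δ = 0 and is monotone in
  δ).
* **Delay prediction** advances the delayed error row to the present by
  iterating the error dynamics under the nominal controller and the
  known target sequence with the interaction torque omitted:
  `e_{k+1} = A e_k + B u_k + (A t*_k − t*_{k+1})`, `u_k = −Lp e_p − Lv e_v`,
  for δ/dt steps. The omitted torque and the conflation of the
  partner-referenced error with the controller's own error are what
  make the prediction imperfect; both effects saturate at the
  closed-loop settling time (~40 ms), so prediction quality plateaus
  between 180 and 540 ms rather than degrading further.

At δ = 0 the three strategies are arithmetically identical, and trial
seeds do not depend on the strategy, so their δ = 0 trials are
bitwise-equal.

## Parameters

| parameter | value | units | why |
|---|---|---|---|
| `dt` | 0.01 | s | recorded-data rate; one loop for plant, controller, estimator |
| `I` | 0.002 | kg·m² | wrist + handle inertia of the rig |
| `(w_p, w_v, r)` | (1, 0, 0.1) | — | gives Lp = 2.38 Nm/rad, Lv = 0.11 Nm·s/rad: a ~2.5 Hz closed loop, noiseless solo floor 1.2e−3 rad (0.4 % of amplitude), mid-skill solo RMSE ≈ 2° |
| process accel SD | 30 | rad/s² | the constant-velocity prior must stay diffuse: the haptic channel error is autocorrelated (it carries the partner's filtered estimate), and a long-memory filter over-accumulates it; 30 rad/s² keeps the δ=0 dyad better than solo across the whole skill range |
| `Σ_zk` | (5°)² | rad² | mid-skill scale: skilled agents down-weight the compliant channel, low-skill agents lean on it — the gradient behind the skill-dependent no-compensation instability |
| `infer_alpha` | 0.1 | — | EMA factor of the torque-trend velocity (~0.1 s lag) |
| divergence guard | 10 | rad | truncates runaway trials without float overflow; truncated series keep their metrics and a flag |
| skill range | 1–6 | deg RMSE | cohort draws are log-uniform (skill spreads multiplicatively); a synthetic stand-in, the experimental per-participant values being available only graphically |
| SPARC | 10 Hz / 0.05 / pad 4 | — | published defaults of the spectral-arc-length metric |
| cross-correlation | ±2 s window, z-scored | — | argmax of the normalised cross-correlation; ties toward zero lag |

The weights, process noise and `Σ_zk` were calibrated once against the
model's stated premises (floor ≪ amplitude, mid-skill solo RMSE 1–3°,
δ=0 dyad benefit at every skill, skill-graded delay instability) and
frozen; `scripts/calibrate_defaults.py` reproduces the sweep.

## Protocol and cohort

A session is six blocks of ten 30 s trials: block 0 solo, blocks 1–5
coupled with increasing perturbation; each block has seven interaction
trials (averaged into the block metric) and three solo washout trials
(simulated for protocol fidelity, excluded from summaries). A cohort is
20 simulated participants whose solo-RMSE targets are drawn log-uniform
over 1–6° and mapped to visual-noise variances through the empirical
error-to-noise map (solo simulations over a variance grid, isotonic-
corrected if sampling noise dents monotonicity, log-log interpolated,
boundary-slope extrapolated with a warning). Trial seeds derive from
(base seed, participant, block, trial), never from the strategy.

## Metrics

RMSE is reported in degrees. SPARC is computed on the speed profile
(negative spectral arc length of the unit-peak magnitude spectrum up to
an adaptive cutoff). The cross-correlation delay is the lag maximising
the z-scored target/response correlation. Co-contraction is
`min(τ_f, |τ_e|)` on torques calibrated from EMG by per-muscle linear
regression, normalised per participant to [0, 1] across trial means.
The simulator has no muscle model, so cohort co-contraction columns are
produced from synthetic EMG driven by each trial's control torque at a
fixed overlap level — they exercise the measurement pipeline, not a
co-activation strategy.

## What the synthetic data does and does not emulate

The generators reproduce the study's structure — trial/block counts,
perturbation ladders, a skill-spread cohort, plateau-protocol EMG with
a known linear torque map plus noise — but not the humans: no learning
across blocks, no fatigue, no physiological EMG spectrum, no
co-activation response to noise, and cohort skills are draws, not the
experimental participants. Passing tests therefore validate the
machinery and the model's internal logic, not behavioural predictions
about people.

## Numerical choices

The inner loop is a numba kernel mirrored, operation for operation, by
the public single-step functions; a parity test holds them to 1e−10.
Covariances are symmetrised after every update. The delay buffer holds
the initial state during warm-up. Wilcoxon Z uses mid-ranks,
zero-difference removal and the plain normal approximation *without*
continuity correction (the convention pinned by W = 210, Z = 3.9199 at
n = 20); the F-test is two-sided; Hommel adjustment is delegated to
statsmodels.

## Known limitations

* With the haptic channel fully discounted, the mechanically delayed
  band torque still degrades tracking by ~25–40 % at 180–540 ms (the
  delayed coupling is non-passive and the wrist controller's stiffness
  is comparable to the band's). The as-noise strategy therefore floors
  near solo-plus-drag rather than at the unperturbed dyad level, and
  its cohort medians sit ~30–50 % above the δ=0 median at the two
  highest delays.
* Cohort RMSE variance is dominated by the skill ladder in every
  condition; variance-based tests separate delay-prediction from
  no-compensation (whose tail blows up) but not from as-noise.
* Prediction error saturates at the closed-loop time scale, so the
  delay-prediction medians plateau between 180 and 540 ms.
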