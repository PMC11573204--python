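"""Calibration sweep behind the frozen model defaults.

Reproduces the evaluations used to choose the controller cost weights,
the target-prior process noise and the band-compliance variance, by
scoring each candidate configuration against the model's stated
premises:

* a noiseless solo agent tracks with an error far below the target
  amplitude;
* a mid-skill solo agent lands at 1-3 deg RMSE;
* a matched-skill dyad at zero delay beats solo across the skill range;
* without compensation, a 540 ms delay degrades low-skill agents much
  more than high-skill ones.

Run:  python scripts/calibrate_defaults.py
"""

import numpy as np

from hapticdyad.agent_model import CostWeights, PlantParams, lqr_gains
from hapticdyad.behaviour_metrics import rmse
from hapticdyad.compensation import StrategySpec
from hapticdyad.coupling import CouplingSpec
from hapticdyad.protocol import AgentConfig, run_trial


def median_rmse(agent, partner=None, coupling=None, strategy=None, seeds=10):
    vals = []
    for k in range(seeds):
        rec = run_trial(agent, partner, coupling or CouplingSpec(),
                        strategy or StrategySpec("none"), seed=k)
        vals.append(rmse(rec.q[0, :rec.filled], rec.target[:rec.filled]))
    return float(np.median(vals))


def main() -> None:
    plant = PlantParams()
    for r_eff in (0.01, 0.03, 0.1, 1.0):
        w = CostWeights(1.0, 0.0, r_eff)
        g = lqr_gains(plant, w)
        floor = median_rmse(AgentConfig(sigma_zv=1e-12, weights=w), seeds=1)
        print(f"\nr={r_eff:g}  Lp={g.lp:.2f} Nm/rad  Lv={g.lv:.3f}  "
              f"noiseless floor={np.deg2rad(floor):.2e} rad")
        for sd_deg in (3.0, 7.0, 15.0):
            var = float(np.deg2rad(sd_deg) ** 2)
            a = AgentConfig(sigma_zv=var, weights=w)
            p = AgentConfig(sigma_zv=var, weights=w)
            solo = median_rmse(a)
            dyad0 = median_rmse(a, p)
            none540 = median_rmse(a, p, CouplingSpec(delay=0.54),
                                  StrategySpec("none"))
            print(f"  visual SD {sd_deg:4.1f} deg: solo {solo:5.2f}  "
                  f"dyad0 {dyad0:5.2f}  nocomp@540 {none540:5.2f}")


if __name__ == "__main__":
    main()
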