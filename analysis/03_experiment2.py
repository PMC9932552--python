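#!/usr/bin/env python
"""Run the blackout experiment (Experiment 2) through the model.

Crosses the 18 heading-switch conditions with four blackout conditions on
the 32-frame protocol (no blackout; one blank frame before the switch; one
at the switch, lengthening the trial; and a blackout from one frame after
the switch to the end of the trial).  Writes per-trial results and the
bias/precision tables, collapsed across switch-angle sign, under
results/experiment2/.

Finding to look for: bias is elevated in the postblackout condition
relative to the preblackout and noblackout conditions, which do not differ
from each other — and the midblackout condition shows no elevation (the
model's known divergence from human judgments).
"""

import argparse
from pathlib import Path

from headingflow.analysis import collapse_by_sign
from headingflow.experiment import ExperimentPlan, run_experiment
from headingflow.model import build_templates

OUT = Path(__file__).resolve().parents[1] / "results" / "experiment2"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    plan = ExperimentPlan(experiment=2, n_reps=args.reps, base_seed=args.seed)
    bank = build_templates(plan.scene.resolution, plan.scene)
    bundle = run_experiment(plan, bank=bank)

    bundle.trials.to_csv(OUT / "trials.csv", index=False)
    bundle.bias_table.to_csv(OUT / "bias_table.csv", index=False)
    collapsed = collapse_by_sign(bundle.bias_table, "bias")
    collapsed.to_csv(OUT / "bias_table_collapsed.csv", index=False)
    bundle.precision_table.to_csv(OUT / "precision_table.csv", index=False)

    means = bundle.bias_trials.groupby("condition_label")["bias"].mean()
    print("mean signed bias by blackout condition:")
    for label in ("noblackout", "preblackout", "midblackout", "postblackout"):
        print(f"  {label:13s}: {means[label]:+.2f} deg")


if __name__ == "__main__":
    main()
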