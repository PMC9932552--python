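#!/usr/bin/env python
"""Random parameter search and the drive-scale calibration.

Samples model parameters uniformly from the neurophysiologically motivated
intervals (MT radius 2-12.5 deg, MSTd radius 7.5-22 deg, decay 0.1-1.0,
averaging constant 0.2-0.8, filter SDs up to 28/35 deg, ceiling 1-150),
scores each candidate on a reduced heading-switch grid against the
attraction pattern (positive bias, growing with |switch angle|, shrinking
with viewing time), and writes the ranked candidates.  Also scores a grid
of drive-scale values, the model's one input-normalization constant.

Run with --iters 0 to skip the search and only run the calibration.
"""

import argparse
from pathlib import Path

from headingflow.experiment import SearchSpace, calibrate_drive_scale, parameter_search

OUT = Path(__file__).resolve().parents[1] / "results" / "search"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--iters", type=int, default=8)
    parser.add_argument("--reps", type=int, default=1)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    if args.iters > 0:
        ranked = parameter_search(
            SearchSpace(), n_iter=args.iters, seed=args.seed, n_reps=args.reps
        )
        ranked.to_csv(OUT / "candidates.csv", index=False)
        print("top parameter candidates (score: 0 = perfect attraction pattern):")
        print(ranked.head(3).to_string(index=False))

    calib = calibrate_drive_scale(n_reps=args.reps, base_seed=args.seed)
    calib.to_csv(OUT / "drive_scale.csv", index=False)
    print("\ndrive-scale calibration:")
    print(calib.to_string(index=False))


if __name__ == "__main__":
    main()
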