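"""Replicate studies: headline rates, slope coverage, distance calibration,
feature ablation.  The heavier counterpart of the acceptance suite, with
knobs to scale the replicate counts.

Usage: python analysis/04_replicate_studies.py [--seed 11] [--out results]
       [--replicates 50] [--coverage-replicates 500] [--ablation-seeds 20]
"""

import argparse
import json
from pathlib import Path

from mgmv.studies import (feature_ablation_accuracies, headline_rates,
                          held_out_distance_calibration, slope_coverage)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--replicates", type=int, default=50)
    ap.add_argument("--coverage-replicates", type=int, default=500)
    ap.add_argument("--ablation-seeds", type=int, default=20)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = {
        "headline": headline_rates(n_replicates=args.replicates, B=200,
                                   seed=args.seed),
        "coverage": slope_coverage(n_replicates=args.coverage_replicates,
                                   seed=args.seed),
        "distance_calibration": held_out_distance_calibration(seed=args.seed),
        "ablation": feature_ablation_accuracies(n_seeds=args.ablation_seeds,
                                                seed=args.seed),
    }
    (args.out / "replicate_studies.json").write_text(
        json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
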