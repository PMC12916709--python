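"""Coverage calibration of the smoothed-bootstrap confidence intervals.

Draws synthetic single-input single-output CRS datasets with known
efficiency, bootstraps each, and reports how often the reflected
(bias-corrected-basic) 95% interval covers the true score. The long-run
coverage of this experiment is about 0.92; single runs of a few hundred
datasets carry a Monte-Carlo standard error of 1-2 percentage points.

Usage: python analysis/04_bootstrap_calibration.py [--seed 777]
       [--datasets 100] [--dmus 20] [--bootstrap 500]
       [--out results/bootstrap_calibration.json]
"""

import argparse
import json
from pathlib import Path

from hospdea.bootstrap import BootstrapConfig, derive_seed, smoothed_bootstrap
from hospdea.synthetic import SIMPLE_CRS_TECH, generate_dmu_sample


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=777)
    ap.add_argument("--datasets", type=int, default=100)
    ap.add_argument("--dmus", type=int, default=20)
    ap.add_argument("--bootstrap", type=int, default=500)
    ap.add_argument("--out", default="results/bootstrap_calibration.json")
    args = ap.parse_args()

    hits = total = 0
    bias_nonneg = 0
    for ds in range(args.datasets):
        dmus, theta_true = generate_dmu_sample(
            SIMPLE_CRS_TECH, args.dmus, seed=derive_seed(args.seed, "data", ds)
        )
        ests = smoothed_bootstrap(
            dmus, "crs",
            BootstrapConfig(B=args.bootstrap,
                            seed=derive_seed(args.seed, "boot", ds),
                            ci_style="bias-corrected-basic"),
        )
        for est, truth in zip(ests, theta_true):
            hits += est.ci_low <= truth <= est.ci_high
            bias_nonneg += est.bias >= 0
            total += 1

    summary = {
        "datasets": args.datasets,
        "dmus_per_dataset": args.dmus,
        "replicates": args.bootstrap,
        "nominal_level": 0.95,
        "coverage": hits / total,
        "bias_nonnegative_fraction": bias_nonneg / total,
    }
    dest = Path(args.out)
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
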