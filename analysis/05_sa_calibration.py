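"""Annealer calibration burden: iteration count and penalty factor effects.

On 20 independent 100-unit landscapes, measures the best-of-10
annealer's relative cost gap over the certified optimum as the iteration
budget grows (1e3 / 1e4 / 1e5), plus the two penalty-factor extremes:
factor 0 (no reason to select anything; the empty solution is optimal)
and factor 125 (targets should always be met). The exact route needs
none of this tuning — that asymmetry is the practical argument for it.
Writes results/sa_calibration.json.
"""

import argparse
import json
from pathlib import Path

from minset.study import calibration_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    res = calibration_study(master_seed=args.seed)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "sa_calibration.json").write_text(json.dumps(res, indent=2) + "\n")

    print("median cost gap over the certified optimum, best-of-10 annealing:")
    for it, gap in res["median_gap_pct"].items():
        print(f"  {it:>7} iterations: {gap:6.1f}%  "
              f"({res['n_feasible'][it]}/{res['n_instances']} instances feasible)")
    print(f"penalty factor 0: empty solution in {res['spf0_empty_rate']:.0%} of instances")
    print(f"penalty factor 125: all targets met in {res['spf125_target_rate']:.0%} of instances")


if __name__ == "__main__":
    main()
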