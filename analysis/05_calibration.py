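"""Monte-Carlo checks of the peak caller: null FDR calibration and
planted-site recovery.

Part one runs the caller on site-free ~5,000-probe arrays and reports the
realized false-discovery proportion among peaks passing FDR <= 0.05. Part two
repeats the default planted-site condition (20 sites, 6-fold enrichment,
noise sd 0.3) and reports recall, precision and summit accuracy after the
default filters. Scaled-down replicate counts here keep this driver quick;
the full-size versions run in the test suite and acceptance script.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from esnacchip.evaluation import null_false_discovery_proportions, planted_recovery_trial

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--n-null", type=int, default=50)
    ap.add_argument("--n-recovery", type=int, default=20)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "calibration.json")
    args = ap.parse_args()

    fdps = null_false_discovery_proportions(args.n_null, base_seed=args.seed * 1000)
    print(f"null arrays                  {args.n_null}")
    print(f"mean realized FDP @ FDR<=0.05 {fdps.mean():.3f}")

    metrics = [planted_recovery_trial(args.seed * 2000 + i) for i in range(args.n_recovery)]
    recall = float(np.mean([m["recall"] for m in metrics]))
    precision = float(np.mean([m["precision"] for m in metrics]))
    summit = float(np.mean([m["summit_within_spacing"] for m in metrics]))
    print(f"recovery arrays              {args.n_recovery}")
    print(f"site recall                  {recall:.3f}")
    print(f"peak precision               {precision:.3f}")
    print(f"summit within one spacing    {summit:.3f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({
        "null_mean_fdp": {"value": float(fdps.mean()), "n": args.n_null},
        "site_recall": {"value": recall, "n": args.n_recovery},
        "site_precision": {"value": precision, "n": args.n_recovery},
        "summit_within_spacing": {"value": summit, "n": args.n_recovery},
    }, indent=2) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
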