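#!/usr/bin/env python
"""Net displacement and movement rate for the Experiment-2 cohort.

Intermittently observed flies: per-fly net displacement direction from
the release point (Rayleigh and Hermans-Rasson tests of a common
heading bias), total distance moved, and mean movement rate in m/h.
Writes results/experiment2/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from qflytrack.circular_stats import hermans_rasson_test, rayleigh_test
from qflytrack.track_io import derive_steps, movement_rate, read_tracks

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fixtures", type=Path,
                    default=ROOT / "results" / "fixtures")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "experiment2")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = read_tracks(str(args.fixtures / "experiment2.csv"), dialect="xy",
                        experiment="periodic")
    usable = [p for p in paths if len(p.fixes) >= 2]
    headings = np.concatenate([derive_steps(p, 0.0).headings for p in usable])
    rates = [movement_rate(p) for p in usable]
    totals = [derive_steps(p, 0.0).lengths.sum() for p in usable]

    out = {
        "n_flies": len(usable),
        "flight_directions": {
            "n": int(headings.size),
            "rayleigh_p": rayleigh_test(headings).p_value,
            "hermans_rasson_p": hermans_rasson_test(
                headings, mc_reps=9999, seed=args.seed).p_value,
        },
        "total_distance_m": {"mean": float(np.mean(totals)),
                             "se": float(np.std(totals, ddof=1)
                                         / np.sqrt(len(totals)))},
        "speed_m_per_h": {"mean": float(np.mean(rates)),
                          "se": float(np.std(rates, ddof=1)
                                      / np.sqrt(len(rates)))},
    }
    (args.out / "experiment2.json").write_text(json.dumps(out, indent=1))

    print(f"{out['n_flies']} flies observed over <=26 h")
    print(f"total distance: {out['total_distance_m']['mean']:.1f} +- "
          f"{out['total_distance_m']['se']:.1f} m")
    print(f"movement rate: {out['speed_m_per_h']['mean']:.2f} +- "
          f"{out['speed_m_per_h']['se']:.2f} m/h")
    print(f"direction bias: Rayleigh p="
          f"{out['flight_directions']['rayleigh_p']:.3f}, HR p="
          f"{out['flight_directions']['hermans_rasson_p']:.3f}")


if __name__ == "__main__":
    main()
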