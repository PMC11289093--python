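#!/usr/bin/env python
"""Descriptive movement statistics for the Experiment-1 cohort.

Circular tests of flight directions (Rayleigh, Hermans-Rasson,
Watson-Williams across flies) and turning angles (plus 45-degree
quadrant and left/right / forward/backward chi-squared bias tests),
step-length summaries, the binned step-frequency power fit, and mean
movement rates.  Reads results/fixtures/, writes results/descriptive/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from qflytrack.circular_stats import (CircSample, hermans_rasson_test,
                                      mean_direction_and_R,
                                      quadrant_bias_tests, rayleigh_test,
                                      vonmises_kappa, watson_williams_test)
from qflytrack.step_summaries import bin_steps, path_summaries, power_fit
from qflytrack.track_io import derive_steps, movement_rate, read_tracks

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fixtures", type=Path,
                    default=ROOT / "results" / "fixtures")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "descriptive")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = read_tracks(str(args.fixtures / "experiment1.csv"), dialect="xy")
    series = [derive_steps(p) for p in paths]
    headings = np.concatenate([s.headings for s in series])
    turns = np.concatenate([s.turning_angles for s in series])

    out = {}
    mu, R = mean_direction_and_R(CircSample(headings))
    out["flight_directions"] = {
        "n": int(headings.size), "mean_direction_rad": mu, "R": R,
        "rayleigh_p": rayleigh_test(headings).p_value,
        "hermans_rasson_p": hermans_rasson_test(
            headings, mc_reps=9999, seed=args.seed).p_value,
    }
    ww = watson_williams_test([s.headings for s in series if s.n_steps >= 2])
    out["watson_williams"] = {"F": ww.statistic, "df": list(ww.df),
                              "p": ww.p_value}
    mu_t, R_t = mean_direction_and_R(CircSample(turns))
    out["turning_angles"] = {
        "n": int(turns.size), "mean_rad": mu_t, "R": R_t,
        "kappa": vonmises_kappa(turns),
        "rayleigh_p": rayleigh_test(turns).p_value,
        "hermans_rasson_p": hermans_rasson_test(
            turns, mc_reps=9999, seed=args.seed + 1).p_value,
        "quadrant_tests": [json.loads(r.to_json())
                           for r in quadrant_bias_tests(turns)],
    }
    out["summaries"] = path_summaries(series)
    out["movement_rate_m_per_h"] = {
        "per_fly_mean": float(np.mean([movement_rate(p) for p in paths]))}

    binned = bin_steps(np.concatenate([s.lengths for s in series]))
    binned.to_csv(args.out / "binned_steps.csv", index=False)
    pf = power_fit(binned)
    out["step_frequency_power_fit"] = asdict(pf)

    (args.out / "descriptive.json").write_text(json.dumps(out, indent=1))

    s = out["summaries"]
    print(f"steps: n={s['steps']['n']}, mean={s['steps']['mean']:.2f} m, "
          f"median={s['steps']['median']:.2f} m")
    print(f"paths: {s['path_totals']['mean']:.1f} +- "
          f"{s['path_totals']['se']:.1f} m (range "
          f"{s['path_totals']['min']:.1f}-{s['path_totals']['max']:.1f} m)")
    print(f"flight directions: Rayleigh p={out['flight_directions']['rayleigh_p']:.3f}, "
          f"HR p={out['flight_directions']['hermans_rasson_p']:.3f}; "
          f"Watson-Williams F={ww.statistic:.2f} df={ww.df} p={ww.p_value:.2g}")
    print(f"turning angles: R={R_t:.2f} kappa={out['turning_angles']['kappa']:.2f}, "
          f"Rayleigh p={out['turning_angles']['rayleigh_p']:.2g}")
    print(f"power fit: freq = {pf.a:.4f} * dist^{pf.b:.3f} (R2={pf.r2:.3f})")


if __name__ == "__main__":
    main()
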