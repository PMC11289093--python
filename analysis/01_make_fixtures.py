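#!/usr/bin/env python
"""Generate the synthetic track cohorts every later analysis consumes.

Writes an Experiment-1 style cohort (20 flies tracked continuously for
10-12 flights each, two-state reference HMM, 0.1 m position jitter)
and an Experiment-2 style cohort (10 flies observed at twice-daily
radar sweeps over 26 h) under results/fixtures/, each with its YAML
spec sidecar so the fixture can be regenerated bit-identically.
"""

import argparse
from pathlib import Path

from qflytrack.synthetic_data import (SyntheticSpec, make_experiment1_fixture,
                                      make_experiment2_fixture, write_fixture)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "fixtures")
    args = ap.parse_args()

    spec1 = SyntheticSpec(generator="hmm", n_paths=20, steps_per_path=(10, 12),
                          seed=args.seed, noise_sd=0.1)
    paths1, states = make_experiment1_fixture(spec1)
    files = write_fixture(paths1, spec1, args.out, states=states,
                          stem="experiment1")
    n_steps = sum(p.n_steps for p in paths1)
    print(f"experiment 1: {len(paths1)} flies, {n_steps} steps "
          f"-> {files['tracks']}")

    spec2 = SyntheticSpec(generator="experiment2", n_paths=10,
                          steps_per_path=0, seed=args.seed + 1, noise_sd=0.1)
    paths2 = make_experiment2_fixture(spec2)
    files2 = write_fixture(paths2, spec2, args.out, stem="experiment2")
    n_fix = sum(len(p.fixes) for p in paths2)
    print(f"experiment 2: {len(paths2)} flies, {n_fix} fixes over <=26 h "
          f"-> {files2['tracks']}")


if __name__ == "__main__":
    main()
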