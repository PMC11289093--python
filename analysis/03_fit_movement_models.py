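#!/usr/bin/env python
"""Fit the three movement models to the Experiment-1 cohort and compare.

RW (gamma steps, uniform turning), CRW (gamma steps, von Mises
turning), and the two-state HMM (gamma + von Mises per state, shared
transition matrix, multi-start ML) are fitted to the same step series;
their log-likelihoods share one structure, so AIC differences are
meaningful.  The HMM is then Viterbi-decoded to label each step
within-tree (state 1) or between-tree (state 2).  Writes
results/models/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
import yaml

from qflytrack.movement_models import fit_crw, fit_hmm, fit_rw, viterbi_states
from qflytrack.track_io import derive_steps, read_tracks

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-starts", type=int, default=25)
    ap.add_argument("--fixtures", type=Path,
                    default=ROOT / "results" / "fixtures")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "models")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = read_tracks(str(args.fixtures / "experiment1.csv"), dialect="xy")
    series = [derive_steps(p) for p in paths]

    fits = {
        "rw": fit_rw(series),
        "crw": fit_crw(series),
        "hmm": fit_hmm(series, n_starts=args.n_starts, seed=args.seed),
    }
    table = {name: {"loglik": f.loglik, "k": f.n_params, "aic": f.aic,
                    "model": f.model.to_dict()}
             for name, f in fits.items()}
    (args.out / "fits.json").write_text(json.dumps(table, indent=1))
    with open(args.out / "fitted_models.yaml", "w") as fh:
        yaml.safe_dump({k: v.model.to_dict() for k, v in fits.items()}, fh)

    rows = []
    for s in series:
        if s.n_steps == 0:
            continue
        for t, st in enumerate(viterbi_states(fits["hmm"].model, s)):
            rows.append((s.fly_id, t, int(st) + 1))
    pd.DataFrame(rows, columns=["fly_id", "step", "state"]).to_csv(
        args.out / "viterbi_states.csv", index=False)

    for name, f in fits.items():
        print(f"{name:>4}: loglik={f.loglik:9.2f}  k={f.n_params:2d}  "
              f"AIC={f.aic:9.2f}")
    best = min(fits, key=lambda k: fits[k].aic)
    print(f"best model by AIC: {best}")
    h = fits["hmm"].model
    for i, s in enumerate(h.states, 1):
        print(f"state {i}: step {s.step_mean:.2f} +- {s.step_sd:.2f} m, "
              f"turn mean {s.turn_mean:+.2f} rad, kappa {s.turn_kappa:.2f}")


if __name__ == "__main__":
    main()
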