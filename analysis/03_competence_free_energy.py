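#!/usr/bin/env python
"""Reaction-competence statistics over the synthetic replica trajectories.

Pools the 8 replicas, recovers the planted 9.1% competent fraction, attaches
a leave-one-out (jackknife over replicas) error bar, and converts the
fraction to the free-energy cost of reaching a reaction-competent pose,
ΔG = -RT ln f at 303 K.  Writes results/competence.json.
"""

import json
from pathlib import Path

from ketopose.model_io import read_trajectory
from ketopose.stereo import CompetenceCriteria, competence_summary

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    tdir = SCRATCH / "inputs" / "trajectories"
    trajs = [read_trajectory(p, fmt="pdb", replica_id=p.stem)
             for p in sorted(tdir.glob("replica_*.pdb"))]
    s = competence_summary(trajs, CompetenceCriteria(), temperature=303.0)
    payload = {
        "percent_competent": s.percent,
        "per_replica_percent": [100 * f for f in s.per_replica_fractions],
        "jackknife_stderr_percent": 100 * s.loo_stderr,
        "delta_g_kcal_mol": s.delta_g,
        "temperature_K": s.temperature,
        "n_frames": s.n_frames,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "competence.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"competent: {s.percent:.2f}% +- {100 * s.loo_stderr:.2f}% "
          f"of {s.n_frames} frames -> ΔG = {s.delta_g:.2f} kcal/mol at 303 K "
          "(planted: 9.1%, published cost for the most reactive "
          "isomer-conformer: 1.4 kcal/mol)")


if __name__ == "__main__":
    main()
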