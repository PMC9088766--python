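#!/usr/bin/env python
"""Generate every synthetic input consumed by the later analysis steps.

Bulky intermediates (trajectories, umbrella windows, peak lists) go under
scratch/inputs/ -- they are regenerated on demand and are not part of the
curated outputs; only small summary tables land in results/.

  scratch/inputs/poses.csv           docking-pose table, two-cluster mixture
  scratch/inputs/trajectories/*.pdb  8 replicas with a planted 9.1%%
                                     competent fraction (the value observed
                                     for the most reactive isomer-conformer)
  scratch/inputs/windows/            umbrella windows, quartic double well
  scratch/inputs/titration/          fast-exchange HSQC peak lists + manifest
"""

import json
from pathlib import Path

import pandas as pd

from ketopose.model_io import write_trajectory, write_window_file
from ketopose.synthetic import (PoseClusterMix, PotentialSpec, TitrationSpec,
                                TrajectorySpec, gen_competence_trajectory,
                                gen_pose_table, gen_titration_peaklists,
                                gen_umbrella_samples)
from ketopose.triage import poses_to_frame
from ketopose.wham import window_ladder

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "scratch" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    poses, labels = gen_pose_table(160, PoseClusterMix(p_first=0.3), seed=SEED)
    poses_to_frame(poses).to_csv(OUT / "poses.csv", index=False)
    print(f"poses: {len(poses)} written ({(labels == 0).sum()} in the "
          "binder-like cluster)")

    tdir = OUT / "trajectories"
    tdir.mkdir(exist_ok=True)
    for i in range(8):
        traj = gen_competence_trajectory(
            TrajectorySpec(1000, 0.091, noise_sd=0.05, seed=SEED + i),
            replica_id=f"r{i}")
        write_trajectory(traj, tdir / f"replica_{i}.pdb", fmt="pdb")
    print("trajectories: 8 replicas x 1000 frames, planted 9.1% competent")

    wdir = OUT / "windows"
    wdir.mkdir(exist_ok=True)
    pot = PotentialSpec("double_well", {"a": 4.0, "b": 1.0})
    windows = gen_umbrella_samples(pot, window_ladder(-1.8, 1.8, 0.1), 50.0,
                                   5000, temperature=303.0, seed=SEED + 100)
    rows = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.txt"
        write_window_file(w, wdir / name)
        rows.append({"file": name, "center_A": w.center,
                     "k_kcal_mol_A2": w.force_constant})
    pd.DataFrame(rows).to_csv(wdir / "windows.csv", index=False)
    print(f"umbrella: {len(windows)} windows, 5000 samples each")

    ndir = OUT / "titration"
    ndir.mkdir(exist_ok=True)
    true_csp = {40: (0.07, 0.35), 41: (0.05, 0.25), 42: (0.09, 0.45),
                43: (0.04, 0.2), 45: (0.03, 0.15), 50: (0.015, 0.08),
                55: (0.005, 0.02), 60: (0.0, 0.0)}
    spec = TitrationSpec(true_csp, kd=0.5, acp_conc=0.5, noise_sd=0.001,
                         broadened_residues=frozenset({45}), seed=SEED + 200)
    series = gen_titration_peaklists(spec)
    manifest = []
    for pl in series:
        name = f"point_{pl.titration_point}.csv"
        pl.peaks.to_csv(ndir / name, index=False)
        manifest.append({"point": pl.titration_point, "ratio": pl.molar_ratio,
                         "file": name})
    pd.DataFrame(manifest).to_csv(ndir / "manifest.csv", index=False)
    (ndir / "true_csp.json").write_text(json.dumps(
        {str(k): v for k, v in true_csp.items()}, indent=2) + "\n")
    print(f"titration: {len(series)} points over ratios "
          f"{[pl.molar_ratio for pl in series]}")


if __name__ == "__main__":
    main()
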