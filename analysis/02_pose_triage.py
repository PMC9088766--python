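#!/usr/bin/env python
"""Triage the docking-pose table with the dual-threshold filter.

Keeps poses with interaction energy < -90 kJ/mol AND Ser42-patch distance
< 9 Å (both strict), mirroring the selection funnel that reduced 160 docked
ACP-KR binding modes to a handful of MD candidates.  Writes
results/triage.csv and prints the pass count.
"""

from pathlib import Path

import pandas as pd

from ketopose.triage import (TriageThresholds, frame_to_poses, poses_to_frame,
                             triage_filter)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    poses = frame_to_poses(pd.read_csv(SCRATCH / "inputs" / "poses.csv"))
    thresholds = TriageThresholds()  # -90 kJ/mol, 9 Å, strict
    kept = triage_filter(poses, thresholds)
    RESULTS.mkdir(exist_ok=True)
    poses_to_frame(kept).to_csv(RESULTS / "triage.csv", index=False)
    print(f"{len(kept)}/{len(poses)} poses pass "
          f"(energy < {thresholds.energy_max} kJ/mol and "
          f"distance < {thresholds.distance_max} Å)")


if __name__ == "__main__":
    main()
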