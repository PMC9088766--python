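#!/usr/bin/env python
"""Hydrogen-bond occupancy of the catalytic contacts over the replicas.

Measures how often the Tyr157 and Ser144 hydroxyls donate a hydrogen bond to
the substrate carbonyl oxygen O9 (the two contacts that poise the carbonyl
for hydride transfer).  Competent frames carry both contacts by
construction, so the direct occupancies echo the planted competent fraction
plus the incompetent frames whose violated criterion was not that contact.
Writes results/hbonds.csv.
"""

from pathlib import Path

import pandas as pd

from ketopose.hbonds import HBondCriteria, Partner, occupancy_table
from ketopose.model_io import read_trajectory

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

PAIRS = [
    (Partner(("K", 157, "OH"), (("K", 157, "HH"),)), Partner(("S", 2, "O9"))),
    (Partner(("K", 144, "OG"), (("K", 144, "HG"),)), Partner(("S", 2, "O9"))),
]


def main() -> None:
    tdir = SCRATCH / "inputs" / "trajectories"
    criteria = HBondCriteria()  # 3.5 Å, 135 deg
    tables = []
    for p in sorted(tdir.glob("replica_*.pdb")):
        traj = read_trajectory(p, fmt="pdb", replica_id=p.stem)
        t = occupancy_table(traj, PAIRS, criteria)
        t["replica"] = p.stem
        tables.append(t)
    merged = (pd.concat(tables)
              .groupby(["donor", "acceptor", "kind"], as_index=False)
              ["occupancy"].mean()
              .sort_values("occupancy", ascending=False))
    RESULTS.mkdir(exist_ok=True)
    merged.to_csv(RESULTS / "hbonds.csv", index=False)
    for _, row in merged.iterrows():
        print(f"{row['donor']} -> {row['acceptor']}: "
              f"{100 * row['occupancy']:.1f}% of frames ({row['kind']})")


if __name__ == "__main__":
    main()
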