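"""Direct and water-mediated hydrogen-bond detection and occupancy tables.

A hydrogen bond is scored geometrically: donor–acceptor distance at most
``da_max`` (default 3.5 Å) and donor–H–acceptor angle at least ``dha_min``
(default 135°) for some hydrogen attached to the donor.  A water bridge is a
single water molecule simultaneously hydrogen-bonded (in either donor or
acceptor role) to one member of each of two groups in the same frame; chains
of two or more waters do not count.  Occupancy is the fraction of trajectory
frames in which a bond (or bridge) is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_io import AtomId, Structure, Trajectory


@dataclass
class HBondCriteria:
    da_max: float = 3.5    # Å, donor-acceptor heavy-atom distance
    dha_min: float = 135.0  # degrees, donor-H-acceptor angle

    def __post_init__(self) -> None:
        if self.da_max <= 0:
            raise ValidationError("da_max must be > 0")
        if not 0.0 < self.dha_min <= 180.0:
            raise ValidationError("dha_min must be in (0, 180]")


@dataclass(frozen=True)
class Partner:
    """A heavy atom that can take part in hydrogen bonds.

    ``hydrogens`` lists attached H atom ids; an empty tuple means the atom
    can only accept.
    """

    atom: AtomId
    hydrogens: tuple[AtomId, ...] = ()


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    cos = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cos))


def _is_hbond(frame: Structure, donor: Partner, acceptor_id: AtomId,
              c: HBondCriteria) -> bool:
    if not donor.hydrogens:
        raise ValidationError(
            f"donor {donor.atom} has no attached hydrogens"
        )
    d = frame.get(donor.atom).position
    a = frame.get(acceptor_id).position
    if float(np.linalg.norm(d - a)) > c.da_max:
        return False
    for h_id in donor.hydrogens:
        h = frame.get(h_id).position
        if _angle_deg(d, h, a) >= c.dha_min:
            return True
    return False


def detect_hbonds(frame: Structure, donors: Sequence[Partner],
                  acceptors: Sequence[AtomId],
                  c: HBondCriteria | None = None) -> set[tuple[AtomId, AtomId]]:
    """All (donor, acceptor) pairs hydrogen-bonded in this frame."""
    c = c or HBondCriteria()
    out = set()
    for donor in donors:
        for acc in acceptors:
            if acc == donor.atom:
                continue
            if _is_hbond(frame, donor, acc, c):
                out.add((donor.atom, acc))
    return out


def _either_role_bond(frame: Structure, x: Partner, y: Partner,
                      c: HBondCriteria) -> bool:
    """H-bond between x and y with either one as the donor."""
    if x.hydrogens and _is_hbond(frame, x, y.atom, c):
        return True
    if y.hydrogens and _is_hbond(frame, y, x.atom, c):
        return True
    return False


def detect_water_bridges(frame: Structure, group_a: Sequence[Partner],
                         group_b: Sequence[Partner],
                         waters: Sequence[Partner],
                         c: HBondCriteria | None = None
                         ) -> set[tuple[AtomId, AtomId, AtomId]]:
    """All (a, water, b) triples bridged by exactly one water molecule."""
    c = c or HBondCriteria()
    for w in waters:
        if not w.hydrogens:
            raise ValidationError(f"water {w.atom} has no hydrogens")
    out = set()
    for w in waters:
        bonded_a = [a for a in group_a if a.atom != w.atom
                    and _either_role_bond(frame, a, w, c)]
        if not bonded_a:
            continue
        bonded_b = [b for b in group_b if b.atom != w.atom
                    and _either_role_bond(frame, b, w, c)]
        for a in bonded_a:
            for b in bonded_b:
                if a.atom != b.atom:
                    out.add((a.atom, w.atom, b.atom))
    return out


def occupancy_table(traj: Trajectory,
                    pairs: Sequence[tuple[Partner, Partner]],
                    c: HBondCriteria | None = None,
                    waters: Sequence[Partner] = ()) -> pd.DataFrame:
    """Per-pair direct (and, when waters are given, water-bridge) occupancy.

    Each pair is counted either-role per frame.  The same pair may be both
    directly bonded and water-bridged in one frame; both kinds are counted.
    Rows are sorted by descending occupancy, ties broken by identifier.
    """
    c = c or HBondCriteria()
    if len(traj) == 0:
        raise ValidationError("occupancy_table needs at least one frame")
    n = len(traj)
    direct = np.zeros(len(pairs))
    bridged = np.zeros(len(pairs))
    for frame in traj:
        for i, (x, y) in enumerate(pairs):
            if _either_role_bond(frame, x, y, c):
                direct[i] += 1
            if waters:
                bridges = detect_water_bridges(frame, [x], [y], waters, c)
                if bridges:
                    bridged[i] += 1
    rows = []
    for i, (x, y) in enumerate(pairs):
        rows.append({"donor": ":".join(map(str, x.atom)),
                     "acceptor": ":".join(map(str, y.atom)),
                     "kind": "direct", "occupancy": direct[i] / n})
        if waters:
            rows.append({"donor": ":".join(map(str, x.atom)),
                         "acceptor": ":".join(map(str, y.atom)),
                         "kind": "water-bridge", "occupancy": bridged[i] / n})
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["occupancy", "donor", "acceptor", "kind"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)
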