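"""Docking-pose triage: anchor distances, threshold filter, stability,
Cα-RMSD and clustering.

Candidate ACP–KR binding modes are triaged on two axes: the externally
supplied docking interaction energy (kJ/mol; the scoring engine is consumed
as an oracle, never re-implemented) and the "Ser42-patch" anchor distance —
ACP Ser42 Cβ to KR Arg38 Cζ — which measures whether the
phosphopantetheine-bearing serine faces the arginine patch that recognizes
its phosphate.  Surviving poses are checked for trajectory stability of the
anchor distance, compared by Cα RMSD after optimal superposition, and
condensed to representative frames by average-linkage clustering on the
pairwise RMSD matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .constants import ATOMIC_MASSES
from .errors import AtomLookupError, IntegrityError, ValidationError
from .model_io import Structure, Trajectory


@dataclass
class PoseRecord:
    """One candidate binding mode with its triage-relevant observables."""

    pose_id: str
    model_id: str
    series: Literal["docking", "IA", "IB"] = "docking"
    interaction_energy: float = math.nan  # kJ/mol, external docking score
    ser42_patch_distance: float = math.nan  # Å
    stable: bool | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.ser42_patch_distance) and self.ser42_patch_distance < 0:
            raise ValidationError("ser42_patch_distance must be >= 0")


@dataclass
class TriageThresholds:
    """Dual-threshold pose filter plus the trajectory-stability criterion."""

    energy_max: float = -90.0        # kJ/mol, keep scores strictly below
    distance_max: float = 9.0        # Å, keep anchors strictly below
    stability_tolerance: float = 0.15
    stability_window_ns: float = 4.0
    stability_reference: Literal["window_mean", "first_value"] = "window_mean"

    def __post_init__(self) -> None:
        if self.distance_max <= 0:
            raise ValidationError("distance_max must be > 0")
        if not 0.0 < self.stability_tolerance < 1.0:
            raise ValidationError("stability_tolerance must be in (0, 1)")
        if self.stability_window_ns <= 0:
            raise ValidationError("stability_window_ns must be > 0")


def ser42_patch_distance(frame: Structure, *, acp_ser: int = 42,
                         kr_arg: int = 38) -> float:
    """Distance (Å) from ACP Ser42 Cβ to KR Arg38 Cζ."""
    cb = frame.find_atom(acp_ser, "CB").position
    cz = frame.find_atom(kr_arg, "CZ").position
    return float(np.linalg.norm(cb - cz))


_GUANIDINIUM = ("CZ", "NH1", "NH2", "NE")


def ser42_arg_com_distance(frame: Structure, arginines: Sequence[int] = (38, 65, 93),
                           *, acp_ser: int = 42,
                           per_residue: bool = False) -> float | list[float]:
    """Distance (Å) from Ser42 Oγ to the arginine-patch guanidinium COM.

    By default the guanidinium atoms (Cζ, Nη1, Nη2, Nε) of all listed
    arginines are pooled into one mass-weighted centre of mass; with
    ``per_residue=True`` a list of per-arginine COM distances is returned
    instead.
    """
    og = frame.find_atom(acp_ser, "OG").position

    def com_of(residues: Sequence[int]) -> np.ndarray:
        positions, masses = [], []
        for res in residues:
            for name in _GUANIDINIUM:
                a = frame.find_atom(res, name)
                positions.append(a.position)
                masses.append(ATOMIC_MASSES.get(a.element.upper(), 12.011))
        w = np.asarray(masses)
        return (np.asarray(positions) * w[:, None]).sum(axis=0) / w.sum()

    if per_residue:
        return [float(np.linalg.norm(og - com_of([r]))) for r in arginines]
    return float(np.linalg.norm(og - com_of(arginines)))


def triage_filter(poses: Sequence[PoseRecord], t: TriageThresholds
                  ) -> list[PoseRecord]:
    """Poses passing BOTH strict thresholds, in input order.

    A pose at exactly the energy or distance threshold is excluded (the
    selection criteria are strict inequalities).
    """
    for p in poses:
        if math.isnan(p.interaction_energy) or math.isnan(p.ser42_patch_distance):
            raise ValidationError(f"pose {p.pose_id}: undetermined triage fields")
    return [p for p in poses
            if p.interaction_energy < t.energy_max
            and p.ser42_patch_distance < t.distance_max]


def stability_flag(distance_series: Sequence[float], timestep_ps: float,
                   t: TriageThresholds) -> bool:
    """Whether the anchor distance is stable over the final window.

    True iff every sample in the last ``stability_window_ns`` deviates by at
    most ``stability_tolerance`` (relative) from the window mean — or, with
    ``stability_reference="first_value"``, from the first sample of the
    window.
    """
    series = np.asarray(distance_series, dtype=float)
    if timestep_ps <= 0:
        raise ValidationError("timestep_ps must be > 0")
    window_ps = t.stability_window_ns * 1000.0
    duration = (len(series) - 1) * timestep_ps
    if duration < window_ps:
        raise ValidationError(
            f"series covers {duration / 1000.0:.3g} ns, shorter than the "
            f"{t.stability_window_ns:g} ns stability window"
        )
    n_window = int(math.floor(window_ps / timestep_ps)) + 1
    tail = series[-n_window:]
    ref = tail.mean() if t.stability_reference == "window_mean" else tail[0]
    if ref == 0:
        return bool(np.all(tail == 0))
    return bool(np.all(np.abs(tail - ref) <= t.stability_tolerance * abs(ref)))


def _matched_ca(a: Structure, b: Structure, chain: str | None
                ) -> tuple[np.ndarray, np.ndarray]:
    sel_a = a.select(atom_name="CA", chain_id=chain)
    sel_b = b.select(atom_name="CA", chain_id=chain)
    key = lambda at: (at.chain_id, at.residue_number)
    map_b = {key(at): at for at in sel_b}
    if len(sel_a) == 0:
        raise IntegrityError("no Cα atoms in selection")
    if {key(at) for at in sel_a} != set(map_b):
        raise IntegrityError("Cα rosters differ between the two structures")
    pa = np.array([at.position for at in sel_a])
    pb = np.array([map_b[key(at)].position for at in sel_a])
    return pa, pb


def ca_rmsd(a: Structure, b: Structure, chain: str | None = None) -> float:
    """Minimal Cα RMSD (Å) after optimal rigid-body superposition.

    Uses the least-squares orthogonal-transform solution (Kabsch, via SVD);
    ``chain`` restricts the selection, e.g. to the ACP chain only.
    """
    pa, pb = _matched_ca(a, b, chain)
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    if len(pa) == 1:
        return 0.0
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / math.sqrt(len(pa)))


@dataclass
class ClusterRepresentative:
    """Medoid frame of one RMSD cluster."""

    frame_index: int
    frame: Structure
    member_indices: list[int]

    @property
    def member_count(self) -> int:
        return len(self.member_indices)


def cluster_poses(traj: Trajectory, n_representatives: int,
                  chain: str | None = None) -> list[ClusterRepresentative]:
    """Average-linkage clustering of frames on the pairwise Cα-RMSD matrix.

    The matrix is cut to ``n_representatives`` clusters; each cluster is
    represented by its medoid (minimal summed RMSD to members; ties broken
    by lowest frame index).  Results are ordered by medoid frame index.
    """
    n = len(traj)
    if n_representatives < 1:
        raise ValidationError("n_representatives must be >= 1")
    if n_representatives > n:
        raise ValidationError("n_representatives cannot exceed the frame count")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = ca_rmsd(traj[i], traj[j], chain)
    if n_representatives == n:
        assignments = np.arange(1, n + 1)
    else:
        z = linkage(squareform(dm, checks=False), method="average")
        assignments = fcluster(z, t=n_representatives, criterion="maxclust")
    reps = []
    for label in sorted(set(assignments.tolist())):
        members = [i for i in range(n) if assignments[i] == label]
        sums = dm[np.ix_(members, members)].sum(axis=1)
        medoid = members[int(np.argmin(sums))]  # argmin takes the lowest index on ties
        reps.append(ClusterRepresentative(medoid, traj[medoid], members))
    reps.sort(key=lambda r: r.frame_index)
    return reps


def poses_to_frame(poses: Sequence[PoseRecord]) -> pd.DataFrame:
    """Pose table as a DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "pose_id": p.pose_id, "model_id": p.model_id, "series": p.series,
        "energy_kJmol": p.interaction_energy,
        "distance_A": p.ser42_patch_distance,
        "stable": p.stable,
    } for p in poses])


def frame_to_poses(df: pd.DataFrame) -> list[PoseRecord]:
    """Inverse of :func:`poses_to_frame` (reads triage CSV tables)."""
    poses = []
    for _, row in df.iterrows():
        stable = row.get("stable")
        if pd.isna(stable):
            stable = None
        elif isinstance(stable, str):
            stable = stable.strip().lower() in ("true", "1", "yes")
        else:
            stable = bool(stable)
        poses.append(PoseRecord(
            pose_id=str(row["pose_id"]), model_id=str(row["model_id"]),
            series=str(row.get("series", "docking")),
            interaction_energy=float(row["energy_kJmol"]),
            ser42_patch_distance=float(row["distance_A"]),
            stable=stable,
        ))
    return poses
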