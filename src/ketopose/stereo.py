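"""Substrate stereochemistry and the reaction-competence statistic.

The cyclized octaketide can exist as four C7/C12 stereoisomers, each with two
low-energy chair conformers (C7–OH axial or equatorial): eight
isomer-conformers in total.  Hydride delivery from NADPH to the C9 carbonyl
can occur on either prochiral face; attack from the Re face yields the
S-alcohol (pro-S attack).  A trajectory frame is "reaction competent" when
the hydride, the catalytic Tyr/Ser hydroxyls and the carbonyl satisfy a set
of distance cutoffs and the hydride sits on the required face.  The fraction
of such frames, pooled over replicas, converts to a free-energy cost
ΔG = −RT·ln(f); replicate scatter is quantified by a leave-one-out jackknife.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .errors import DegenerateGeometryError, ValidationError
from .model_io import AtomId, Structure, Trajectory

Face = Literal["pro-S", "pro-R"]


@dataclass(frozen=True)
class IsomerConformer:
    """One of the eight cyclization isomer-conformers of the octaketide."""

    c7_chirality: Literal["R", "S"]
    c12_chirality: Literal["R", "S"]
    c7_oh_orientation: Literal["axial", "equatorial"]

    @property
    def label(self) -> str:
        suffix = "OHax" if self.c7_oh_orientation == "axial" else "OHeq"
        return f"{self.c7_chirality}{self.c12_chirality}-{suffix}"


@dataclass
class AtomMap:
    """Where the competence-relevant atoms live in a structure.

    Defaults match the roster emitted by the synthetic trajectory generator.
    """

    hydride: AtomId = ("N", 1, "H4N")
    donor_carbon: AtomId = ("N", 1, "C4N")
    c9: AtomId = ("S", 2, "C9")
    o9: AtomId = ("S", 2, "O9")
    c8: AtomId = ("S", 2, "C8")
    c10: AtomId = ("S", 2, "C10")
    tyr_oh: AtomId = ("K", 157, "OH")
    ser_og: AtomId = ("K", 144, "OG")


@dataclass
class CompetenceCriteria:
    """Geometric cutoffs defining a reaction-competent frame.

    The cutoffs stand in for the standard near-attack-conformation contacts:
    hydride within striking distance of the carbonyl carbon, and the
    catalytic Tyr157/Ser144 hydroxyl oxygens within hydrogen-bond range of
    the carbonyl oxygen.  All are configuration-exposed.
    """

    d_hydride_c9_max: float = 3.0
    d_tyr_o9_max: float = 3.5
    d_ser_o9_max: float = 3.5
    required_face: Literal["pro-S", "pro-R", "either"] = "pro-S"
    atom_map: AtomMap = field(default_factory=AtomMap)

    def __post_init__(self) -> None:
        for name in ("d_hydride_c9_max", "d_tyr_o9_max", "d_ser_o9_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class CompetenceSummary:
    """Pooled reaction-competence statistic over a set of replicas."""

    fraction: float
    per_replica_fractions: list[float]
    loo_stderr: float
    delta_g: float | None  # kcal/mol; None when fraction == 0
    temperature: float
    n_frames: int
    n_competent: int

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


_COPLANAR_TOL = 1e-6


def assign_chirality(frame: Structure, center_atom: AtomId,
                     ordered_substituents: Sequence[AtomId]) -> str:
    """R/S label of a tetrahedral centre with caller-supplied priorities.

    ``ordered_substituents`` lists the four substituents in decreasing
    priority.  With the lowest-priority substituent pointing away from the
    viewer, a clockwise 1→2→3 arrangement is R.  No CIP priority engine:
    the caller supplies the order (the substrate's priorities are fixed and
    known, so a general CIP implementation would be disproportionate).
    """
    if len(ordered_substituents) != 4:
        raise ValidationError("exactly 4 substituents required")
    c = frame.get(center_atom).position
    v = [frame.get(a).position - c for a in ordered_substituents]
    # normal of the 1-2-3 plane with the right-hand sense of the priority
    # cycle; the viewer sits opposite substituent 4, so the cycle appears
    # clockwise (R) exactly when the normal points toward substituent 4.
    normal = np.cross(v[1] - v[0], v[2] - v[0])
    d = float(np.dot(normal, v[3]))
    scale = float(np.linalg.norm(normal) * np.linalg.norm(v[3]))
    if scale == 0 or abs(d) / scale < _COPLANAR_TOL:
        raise DegenerateGeometryError(
            f"substituents of {center_atom} are coplanar within tolerance"
        )
    return "R" if d > 0 else "S"


def classify_face(frame: Structure, atom_map: AtomMap | None = None) -> Face:
    """Which prochiral face of the C9 carbonyl the hydride approaches.

    With carbonyl substituent priorities O9 > C8 > C10, the face from which
    that sequence appears clockwise is the Re face, and Re-face hydride
    attack yields the S-alcohol (pro-S).  The side of the carbonyl plane is
    read off the sign of (H−C9)·[(O9−C9)×(C8−C9)]: positive puts the hydride
    on the Si side (pro-R), negative on the Re side (pro-S).
    """
    m = atom_map or AtomMap()
    c9 = frame.get(m.c9).position
    v_o9 = frame.get(m.o9).position - c9
    v_c8 = frame.get(m.c8).position - c9
    v_h = frame.get(m.hydride).position - c9
    n = np.cross(v_o9, v_c8)
    s = float(np.dot(v_h, n))
    scale = float(np.linalg.norm(v_h) * np.linalg.norm(n))
    if scale == 0 or abs(s) / scale < _COPLANAR_TOL:
        raise DegenerateGeometryError("hydride lies in the carbonyl plane")
    return "pro-R" if s > 0 else "pro-S"


def ring_conformer(frame: Structure, ring_atoms: Sequence[AtomId],
                   substituent: AtomId,
                   theta_tol_deg: float = 30.0,
                   axial_tol_deg: float = 45.0,
                   planarity_q: float = 0.1,
                   ) -> tuple[str, str]:
    """Classify a six-membered ring as chair/non-chair and a substituent
    as axial/equatorial, via Cremer–Pople puckering coordinates.

    Returns ``(ring_label, orientation)`` with ring_label in
    {"chair_up", "chair_down", "non_chair"} (up/down by the sign of q3) and
    orientation in {"axial", "equatorial"}.  A ring with total puckering
    amplitude Q < ``planarity_q`` Å, or with θ further than ``theta_tol_deg``
    from 0°/180°, is labelled non_chair — that is a label, not an error.
    """
    if len(ring_atoms) != 6:
        raise ValidationError("ring_conformer requires exactly 6 ring atoms")
    pos = np.array([frame.get(a).position for a in ring_atoms])
    center = pos.mean(axis=0)
    r = pos - center
    j = np.arange(6)
    # mean-plane normal (Cremer-Pople construction)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise DegenerateGeometryError("ring atoms are collinear")
    n /= nn
    z = r @ n
    q2cos = math.sqrt(2 / 6) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2sin = -math.sqrt(2 / 6) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q2 = math.hypot(q2cos, q2sin)
    q3 = math.sqrt(1 / 6) * float(((-1.0) ** j * z).sum())
    big_q = math.hypot(q2, q3)

    if big_q < planarity_q:
        ring_label = "non_chair"
    else:
        theta = math.degrees(math.atan2(q2, q3))  # 0 or 180 for ideal chairs
        if theta <= theta_tol_deg:
            ring_label = "chair_up"
        elif theta >= 180.0 - theta_tol_deg:
            ring_label = "chair_down"
        else:
            ring_label = "non_chair"

    # axial/equatorial: angle between the substituent bond (from its ring
    # carbon) and the ring normal, folded to [0, 90]
    sub_pos = frame.get(substituent).position
    dists = np.linalg.norm(pos - sub_pos, axis=1)
    anchor = pos[int(np.argmin(dists))]
    bond = sub_pos - anchor
    bn = np.linalg.norm(bond)
    if bn == 0:
        raise DegenerateGeometryError("substituent coincides with ring atom")
    cosang = abs(float(bond @ n) / bn)
    angle = math.degrees(math.acos(min(1.0, cosang)))
    orientation = "axial" if angle < axial_tol_deg else "equatorial"
    return ring_label, orientation


def enumerate_isomer_conformers() -> list[IsomerConformer]:
    """All 8 isomer-conformers, in RR/RS/SR/SS then axial/equatorial order."""
    return [
        IsomerConformer(c7, c12, oh)
        for c7, c12 in itertools.product("RS", "RS")
        for oh in ("axial", "equatorial")
    ]


def is_reaction_competent(frame: Structure, criteria: CompetenceCriteria) -> bool:
    """True iff all distance cutoffs hold and the hydride is on the
    required prochiral face."""
    m = criteria.atom_map
    d = lambda a, b: float(np.linalg.norm(frame.get(a).position - frame.get(b).position))
    if d(m.hydride, m.c9) > criteria.d_hydride_c9_max:
        return False
    if d(m.tyr_oh, m.o9) > criteria.d_tyr_o9_max:
        return False
    if d(m.ser_og, m.o9) > criteria.d_ser_o9_max:
        return False
    if criteria.required_face != "either":
        if classify_face(frame, m) != criteria.required_face:
            return False
    return True


def free_energy_from_fraction(f: float, temperature: float = DEFAULT_TEMPERATURE
                              ) -> float:
    """Free-energy cost (kcal/mol) of restricting to a fraction f of frames.

    Returns −R·T·ln(f): the positive cost of confining the system to the
    reaction-competent sub-ensemble.  f must lie in (0, 1].
    """
    if not 0.0 < f <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {f}")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    return -R_KCAL * temperature * math.log(f)


def competence_summary(trajs: Sequence[Trajectory],
                       criteria: CompetenceCriteria,
                       temperature: float = DEFAULT_TEMPERATURE,
                       ) -> CompetenceSummary:
    """Pooled competent-frame fraction with jackknife error and ΔG.

    The fraction pools all frames of all replicas.  The leave-one-out error
    removes one replica at a time (frames within a replica are correlated,
    so resampling is over replicas, not frames) and is the jackknife standard
    error of the pooled fraction.  ΔG = −RT·ln(fraction) is flagged undefined
    (None) when no frame is competent.
    """
    if not trajs:
        raise ValidationError("competence_summary needs at least one trajectory")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    counts = []
    totals = []
    for traj in trajs:
        c = sum(is_reaction_competent(fr, criteria) for fr in traj)
        counts.append(c)
        totals.append(len(traj))
    counts_a = np.array(counts, dtype=float)
    totals_a = np.array(totals, dtype=float)
    n_comp = int(counts_a.sum())
    n_tot = int(totals_a.sum())
    fraction = n_comp / n_tot
    per_replica = (counts_a / totals_a).tolist()

    m = len(trajs)
    if m > 1:
        loo = np.array([
            (counts_a.sum() - counts_a[i]) / (totals_a.sum() - totals_a[i])
            for i in range(m)
        ])
        sd = float(np.std(loo, ddof=1))
        loo_stderr = sd * math.sqrt((m - 1) ** 2 / m)
    else:
        loo_stderr = 0.0

    delta_g = free_energy_from_fraction(fraction, temperature) if fraction > 0 else None
    return CompetenceSummary(
        fraction=fraction, per_replica_fractions=per_replica,
        loo_stderr=loo_stderr, delta_g=delta_g, temperature=temperature,
        n_frames=n_tot, n_competent=n_comp,
    )
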