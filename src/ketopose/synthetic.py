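"""Synthetic inputs with controllable ground truth.

Every downstream stage (triage, competence statistics, H-bond occupancy, CSP
analysis, WHAM) consumes data of the same shape as the study's real inputs;
these generators emit such data with planted, recoverable truth:

* active-site trajectories with an exact pre-noise count of
  reaction-competent frames;
* docking-pose tables drawn from a two-cluster (energy, anchor-distance)
  Gaussian mixture;
* umbrella-window samples drawn exactly (independent rejection sampling)
  from the biased Boltzmann density of a known 1-D potential;
* fast-exchange HSQC titration peak lists from a single-site binding
  isotherm with additive shift noise and optional exchange broadening.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .errors import ValidationError
from .model_io import AtomRecord, PeakList, Structure, Trajectory, WindowFile
from .stereo import CompetenceCriteria
from .triage import PoseRecord

# ---------------------------------------------------------------------------
# Reaction-competence trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    """Recipe for one synthetic active-site trajectory."""

    n_frames: int
    fraction_competent: float
    noise_sd: float = 0.0  # Å, isotropic Gaussian on every coordinate
    anchor_distance_profile: Sequence[float] | None = None  # Ser42-patch Å per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not 0.0 <= self.fraction_competent <= 1.0:
            raise ValidationError("fraction_competent must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# minimal roster: (chain, resnum, resname, atom, element)
_ROSTER = [
    ("N", 1, "NDP", "C4N", "C"),   # nicotinamide donor carbon
    ("N", 1, "NDP", "H4N", "H"),   # transferable hydride
    ("S", 2, "SUB", "C7", "C"),
    ("S", 2, "SUB", "C8", "C"),
    ("S", 2, "SUB", "C9", "C"),
    ("S", 2, "SUB", "C10", "C"),
    ("S", 2, "SUB", "C11", "C"),
    ("S", 2, "SUB", "O9", "O"),
    ("K", 157, "TYR", "OH", "O"),
    ("K", 157, "TYR", "HH", "H"),
    ("K", 144, "SER", "OG", "O"),
    ("K", 144, "SER", "HG", "H"),
    ("A", 42, "SER", "CB", "C"),
    ("K", 38, "ARG", "CZ", "C"),
]
_ATOM_INDEX = {(c, r, a): i for i, (c, r, _, a, _) in enumerate(_ROSTER)}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _base_coords(criteria: CompetenceCriteria, competent: bool,
                 anchor_distance: float, violation_mode: int,
                 face: str) -> np.ndarray:
    """Noise-free coordinates for one frame.

    The carbonyl sits at the origin with O9 along +x and C8/C10 trigonal in
    the xy-plane; the Re face is then the −z side (see stereo.classify_face).
    Competent frames place every contact at 90% of its cutoff so that small
    coordinate noise cannot flip the label; incompetent frames violate one
    criterion (chosen by ``violation_mode``) at 150% of its cutoff or by a
    face flip.
    """
    xyz = np.zeros((len(_ROSTER), 3))

    c9 = np.zeros(3)
    o9 = np.array([1.23, 0.0, 0.0])
    c8 = 1.51 * np.array([math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3), 0.0])
    c10 = 1.51 * np.array([math.cos(2 * math.pi / 3), -math.sin(2 * math.pi / 3), 0.0])
    c7 = c8 + 1.53 * _unit(c8 - c9)
    c11 = c10 + 1.53 * _unit(c10 - c9)

    re_side = np.array([0.0, 0.0, -1.0])  # pro-S approach direction
    sign = -1.0 if face == "pro-R" else 1.0
    approach = sign * re_side

    d_h = 0.9 * criteria.d_hydride_c9_max
    d_tyr = 0.9 * criteria.d_tyr_o9_max
    d_ser = 0.9 * criteria.d_ser_o9_max
    if not competent:
        if violation_mode == 0:
            d_h = 1.5 * criteria.d_hydride_c9_max
        elif violation_mode == 1:
            d_tyr = 1.5 * criteria.d_tyr_o9_max
        elif violation_mode == 2:
            d_ser = 1.5 * criteria.d_ser_o9_max
        else:  # face flip (only disqualifying when a specific face is required)
            if criteria.required_face == "either":
                d_h = 1.5 * criteria.d_hydride_c9_max
            else:
                approach = -approach

    hyd = c9 + d_h * approach
    donor = c9 + (d_h + 1.09) * approach

    tyr_dir = _unit(np.array([0.9, 0.35, 0.25]))
    tyr_o = o9 + d_tyr * tyr_dir
    tyr_h = tyr_o - 1.0 * tyr_dir  # O-H pointing back at O9 (near-linear H-bond)
    ser_dir = _unit(np.array([0.9, -0.35, -0.25]))
    ser_o = o9 + d_ser * ser_dir
    ser_h = ser_o - 1.0 * ser_dir

    ser42_cb = np.array([8.0, 8.0, 8.0])
    arg38_cz = ser42_cb + np.array([anchor_distance, 0.0, 0.0])

    for (chain, res, _, name, _), pos in zip(_ROSTER, [
        donor, hyd, c7, c8, c9, c10, c11, o9,
        tyr_o, tyr_h, ser_o, ser_h, ser42_cb, arg38_cz,
    ]):
        xyz[_ATOM_INDEX[(chain, res, name)]] = pos
    return xyz


def gen_competence_trajectory(spec: TrajectorySpec,
                              criteria: CompetenceCriteria | None = None,
                              replica_id: str = "r0", site_id: str = "A",
                              timestep: float = 1.0) -> Trajectory:
    """Trajectory with exactly round(n·fraction) competent frames pre-noise."""
    criteria = criteria or CompetenceCriteria()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n_comp = int(round(n * spec.fraction_competent))
    competent_idx = set(rng.choice(n, size=n_comp, replace=False).tolist())
    violation_modes = rng.integers(0, 4, size=n)
    face = criteria.required_face if criteria.required_face != "either" else "pro-S"

    profile = spec.anchor_distance_profile
    if profile is not None and len(profile) != n:
        raise ValidationError("anchor_distance_profile length must equal n_frames")

    frames = []
    for i in range(n):
        anchor = float(profile[i]) if profile is not None else 7.0
        xyz = _base_coords(criteria, i in competent_idx, anchor,
                           int(violation_modes[i]), face)
        if spec.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sd, size=xyz.shape)
        atoms = [
            AtomRecord(name, el, resname, res, chain, xyz[k])
            for k, (chain, res, resname, name, el) in enumerate(_ROSTER)
        ]
        frames.append(Structure(atoms, f"{replica_id}_f{i}"))
    return Trajectory(frames, timestep=timestep, replica_id=replica_id,
                      site_id=site_id)


# ---------------------------------------------------------------------------
# 1-D potentials and umbrella-window sampling
# ---------------------------------------------------------------------------


@dataclass
class PotentialSpec:
    """A 1-D potential U(ξ) in kcal/mol.

    Forms: ``harmonic`` (½·k_u·ξ², params ``k``), ``double_well``
    (a·(ξ²−b²)², params ``a``, ``b``; barrier a·b⁴ at ξ=0), ``table``
    (piecewise-linear through ``xi``/``u`` arrays).
    """

    form: Literal["harmonic", "double_well", "table"]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form == "harmonic":
            if self.params.get("k", 0.0) < 0:
                raise ValidationError("harmonic potential is unbounded below (k < 0)")
        elif self.form == "double_well":
            if self.params.get("a", 0.0) <= 0:
                raise ValidationError("double-well potential requires a > 0")
        elif self.form == "table":
            xi = np.asarray(self.params.get("xi", []), dtype=float)
            u = np.asarray(self.params.get("u", []), dtype=float)
            if xi.size < 2 or xi.size != u.size:
                raise ValidationError("table potential needs matching xi/u arrays")
            if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(u))):
                raise ValidationError("table potential must be finite")
        else:
            raise ValidationError(f"unknown potential form {self.form!r}")

    def energy(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.form == "harmonic":
            k = float(self.params.get("k", 0.0))
            return lambda x: 0.5 * k * np.asarray(x) ** 2
        if self.form == "double_well":
            a = float(self.params["a"])
            b = float(self.params.get("b", 1.0))
            return lambda x: a * (np.asarray(x) ** 2 - b ** 2) ** 2
        xi = np.asarray(self.params["xi"], dtype=float)
        u = np.asarray(self.params["u"], dtype=float)
        # linear extrapolation outside the table would be unbounded below if
        # the edge slopes point down; clamp to edge values instead
        return lambda x: np.interp(np.asarray(x), xi, u)


def gen_umbrella_samples(potential: PotentialSpec, centers: Sequence[float],
                         k: float, n_per_window: int,
                         temperature: float = DEFAULT_TEMPERATURE,
                         seed: int = 0,
                         method: Literal["rejection", "metropolis"] = "rejection",
                         burn_in: int = 500,
                         ) -> list[WindowFile]:
    """Draw ξ samples from each biased density ∝ exp(−[U(ξ)+½k(ξ−c)²]/RT).

    ``rejection`` (default) yields exact independent draws using the bias
    Gaussian as proposal; ``metropolis`` runs a random-walk chain with
    ``burn_in`` discarded steps for realism (correlated samples).
    """
    if n_per_window < 1:
        raise ValidationError("n_per_window must be >= 1")
    if k <= 0:
        raise ValidationError("bias force constant must be > 0")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    u = potential.energy()
    rt = R_KCAL * temperature
    rng = np.random.default_rng(seed)
    windows = []
    for c in centers:
        if method == "rejection":
            samples = _rejection_window(u, float(c), k, rt, n_per_window, rng)
        else:
            samples = _metropolis_window(u, float(c), k, rt, n_per_window,
                                         burn_in, rng)
        windows.append(WindowFile(float(c), float(k), samples))
    return windows


def _rejection_window(u, c, k, rt, n, rng) -> np.ndarray:
    """Exact independent draws from exp(-[U + ½k(x-c)²]/RT).

    Rejection sampling against a piecewise-constant envelope of the biased
    density on a fine grid: a steep U(ξ) can shift the biased density far
    from the bias centre, so a bias-Gaussian proposal would be arbitrarily
    inefficient; the envelope tracks the actual density and keeps acceptance
    near one.
    """
    def energy(x):
        return u(x) + 0.5 * k * (x - c) ** 2

    # locate the support: wide coarse scan, keep where density > e^-30
    sigma = math.sqrt(rt / k)
    wide = np.linspace(c - max(6.0, 10 * sigma), c + max(6.0, 10 * sigma), 4001)
    e_wide = energy(wide)
    e_min = float(e_wide.min())
    kept = wide[e_wide - e_min < 30.0 * rt]
    lo, hi = float(kept.min()), float(kept.max())
    pad = (hi - lo) * 0.02 + 1e-6
    grid = np.linspace(lo - pad, hi + pad, 2001)
    dens = np.exp(-(energy(grid) - e_min) / rt)
    # per-interval envelope: interval max of the endpoint densities, padded
    # to cover curvature within the (very narrow) interval
    h = np.maximum(dens[:-1], dens[1:]) * 1.01
    widths = np.diff(grid)
    mass = h * widths
    cdf = np.cumsum(mass)
    cdf /= cdf[-1]

    out = np.empty(0)
    while out.size < n:
        batch = max(int(1.2 * (n - out.size)), 256)
        bins = np.searchsorted(cdf, rng.random(batch))
        x = grid[bins] + widths[bins] * rng.random(batch)
        ratio = np.exp(-(energy(x) - e_min) / rt) / h[bins]
        accept = rng.random(batch) < ratio
        out = np.concatenate([out, x[accept]])
    return out[:n]


def _metropolis_window(u, c, k, rt, n, burn_in, rng) -> np.ndarray:
    def energy(x):
        return u(x) + 0.5 * k * (x - c) ** 2

    step = math.sqrt(rt / k)
    x = c
    e = float(energy(np.array([x]))[0])
    out = np.empty(n)
    total = burn_in + n
    prop = rng.normal(0.0, step, size=total)
    unif = rng.random(total)
    j = 0
    for i in range(total):
        xn = x + prop[i]
        en = float(energy(np.array([xn]))[0])
        if unif[i] < math.exp(min(0.0, -(en - e) / rt)):
            x, e = xn, en
        if i >= burn_in:
            out[j] = x
            j += 1
    return out


# ---------------------------------------------------------------------------
# Titration peak lists
# ---------------------------------------------------------------------------

#: KR/ACP molar ratios of the titration series, preceded by the apo
#: reference point (free labeled ACP before any partner is added).
DEFAULT_RATIOS: tuple[float, ...] = (0.0, 0.08, 0.47, 0.33, 0.67, 1.00,
                                     1.34, 1.67, 2.34)


@dataclass
class TitrationSpec:
    """Ground truth for a fast-exchange HSQC titration."""

    true_csp: dict[int, tuple[float, float]]  # residue -> (Δδ_H, Δδ_N) at saturation, ppm
    kd: float = 0.5            # mM
    acp_conc: float = 0.5      # mM, total labeled-protein concentration
    ratios: Sequence[float] = DEFAULT_RATIOS
    noise_sd: float = 0.0      # ppm, per observed shift
    broadened_residues: frozenset[int] = frozenset()
    broadening_factor: float = 0.5  # per-point intensity multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError("Kd must be > 0")
        if self.acp_conc <= 0:
            raise ValidationError("acp_conc must be > 0")
        if any(r < 0 for r in self.ratios):
            raise ValidationError("ratios must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def bound_fraction(ratio: float, acp_conc: float, kd: float) -> float:
    """Single-site bound fraction of the observed (ACP) species.

    Solves [PL] from the quadratic for totals P₀ = acp_conc,
    L₀ = ratio·acp_conc and dissociation constant Kd (all same units):
    f = ([P₀+L₀+Kd] − √((P₀+L₀+Kd)² − 4·P₀·L₀)) / (2·P₀).
    """
    if acp_conc <= 0:
        raise ValidationError("acp_conc must be > 0")
    if kd < 0 or ratio < 0:
        raise ValidationError("kd and ratio must be non-negative")
    p0 = acp_conc
    l0 = ratio * acp_conc
    b = p0 + l0 + kd
    disc = b * b - 4.0 * p0 * l0
    complex_conc = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    return complex_conc / p0


def gen_titration_peaklists(spec: TitrationSpec) -> list[PeakList]:
    """Fast-exchange peak lists: observed shift = free + f_bound·ΔδSAT.

    Broadened residues lose intensity by ``broadening_factor`` per titration
    point and are dropped from the list once below 10% of their initial
    intensity; Gaussian noise of sd ``noise_sd`` is added to every shift.
    """
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.true_csp)
    free_h = {r: 7.5 + 2.0 * rng.random() for r in residues}
    free_n = {r: 105.0 + 25.0 * rng.random() for r in residues}
    i0 = 1.0

    out = []
    for point, ratio in enumerate(spec.ratios):
        fb = bound_fraction(float(ratio), spec.acp_conc, spec.kd)
        rows = []
        for r in residues:
            dh, dn = spec.true_csp[r]
            h = free_h[r] + fb * dh
            n = free_n[r] + fb * dn
            if spec.noise_sd > 0:
                h += rng.normal(0.0, spec.noise_sd)
                n += rng.normal(0.0, spec.noise_sd)
            intensity = i0
            if r in spec.broadened_residues:
                intensity = i0 * spec.broadening_factor ** point
                if intensity < 0.1 * i0:
                    continue  # peak broadened beyond detection
            rows.append((r, h, n, intensity))
        df = pd.DataFrame(rows, columns=["residue", "shift_H_ppm",
                                         "shift_N_ppm", "intensity"])
        out.append(PeakList(point, float(ratio), df))
    return out


# ---------------------------------------------------------------------------
# Docking-pose tables
# ---------------------------------------------------------------------------


@dataclass
class PoseClusterMix:
    """Two (interaction energy, anchor distance) Gaussian clusters.

    The first cluster models plausible binders (low score, short
    Ser42-patch distance), the second non-binders; ``p_first`` is the
    mixing weight of the first.
    """

    p_first: float = 0.5
    mean_first: tuple[float, float] = (-120.0, 5.0)   # (kJ/mol, Å)
    sd_first: tuple[float, float] = (10.0, 1.0)
    mean_second: tuple[float, float] = (-50.0, 12.0)
    sd_second: tuple[float, float] = (10.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_first <= 1.0:
            raise ValidationError("p_first must be in [0, 1]")


def gen_pose_table(n: int, mixture: PoseClusterMix | None = None, seed: int = 0
                   ) -> tuple[list[PoseRecord], np.ndarray]:
    """Draw n poses from the mixture; returns (poses, ground-truth labels).

    Labels are 0 for the first cluster, 1 for the second; distances are
    clipped at 0 Å.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    mixture = mixture or PoseClusterMix()
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) >= mixture.p_first).astype(int)
    means = np.array([mixture.mean_first, mixture.mean_second])
    sds = np.array([mixture.sd_first, mixture.sd_second])
    draws = rng.normal(means[labels], sds[labels])
    poses = []
    for i in range(n):
        poses.append(PoseRecord(
            pose_id=f"pose{i:04d}",
            model_id=f"M{(i % 20) + 1}",
            series="docking",
            interaction_energy=float(draws[i, 0]),
            ser42_patch_distance=float(max(draws[i, 1], 0.0)),
        ))
    return poses, labels
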