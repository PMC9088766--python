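"""HSQC titration analysis: chemical shift perturbations, binning, broadening.

Per-residue peak movements across a titration are combined into the weighted
average CSP

    δ_AV = sqrt(0.5 * [Δδ(1H)^2 + (0.2 * Δδ(15N))^2])   (ppm)

and classified into the standard perturbation bins: none (δ_AV ≤ 0.02),
yellow (0.02–0.04), orange (0.04–0.06), red (≥ 0.06).  Boundary points at
0.02 and 0.04 ppm resolve to the lower bin.  Residues that vanish during the
titration with decaying intensity are flagged as exchange-broadened; prolines
(no backbone N–H) are reported with an explicit missing marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .model_io import PeakList

BINS = ("none", "yellow", "orange", "red")


@dataclass
class ResidueCSP:
    residue_number: int
    d_shift_H: float  # ppm, may be NaN when the residue is missing
    d_shift_N: float
    delta_av: float
    bin: str          # one of BINS, or "missing"
    broadened: bool


def csp_weighted_average(d_h: float, d_n: float) -> float:
    """Weighted-average CSP (ppm); signs are irrelevant (terms are squared)."""
    return math.sqrt(0.5 * (d_h ** 2 + (0.2 * d_n) ** 2))


def classify_csp(delta_av: float) -> str:
    """Perturbation bin for a δ_AV value (boundaries go to the lower bin)."""
    if delta_av < 0 or math.isnan(delta_av):
        raise ValidationError(f"delta_av must be >= 0, got {delta_av}")
    if delta_av <= 0.02:
        return "none"
    if delta_av <= 0.04:
        return "yellow"
    if delta_av < 0.06:
        return "orange"
    return "red"


@dataclass
class PeakTracks:
    """Per-residue shift/intensity trajectories over a titration series.

    Arrays are (n_points, n_residues); missing peaks are NaN.
    """

    residues: list[int]
    ratios: list[float]
    shift_H: np.ndarray
    shift_N: np.ndarray
    intensity: np.ndarray

    def broadened(self, residue: int) -> bool:
        """Disappeared before the final point with < 50% of initial intensity."""
        j = self.residues.index(residue)
        inten = self.intensity[:, j]
        observed = np.flatnonzero(~np.isnan(inten))
        if observed.size == 0:
            return False
        first, last = observed[0], observed[-1]
        if last == len(self.ratios) - 1:
            return False  # still visible at the end
        return bool(inten[last] < 0.5 * inten[first])


def track_peaks(series: Sequence[PeakList]) -> PeakTracks:
    """Match peaks across titration points by residue number.

    The first list is the reference (apo).  Residues absent at a point are
    recorded as gaps (NaN).
    """
    if not series:
        raise ValidationError("empty titration series")
    residues = sorted({int(r) for pl in series for r in pl.peaks["residue"]})
    idx = {r: j for j, r in enumerate(residues)}
    n_pts = len(series)
    shape = (n_pts, len(residues))
    shift_h = np.full(shape, np.nan)
    shift_n = np.full(shape, np.nan)
    inten = np.full(shape, np.nan)
    for i, pl in enumerate(series):
        # PeakList construction already rejects duplicates; re-check cheaply
        if pl.peaks["residue"].duplicated().any():
            raise IntegrityError(f"duplicate residues at titration point {i}")
        for _, row in pl.peaks.iterrows():
            j = idx[int(row["residue"])]
            shift_h[i, j] = row["shift_H_ppm"]
            shift_n[i, j] = row["shift_N_ppm"]
            inten[i, j] = row["intensity"]
    return PeakTracks(residues, [pl.molar_ratio for pl in series],
                      shift_h, shift_n, inten)


def match_peaks_nearest(reference: PeakList, other: PeakList,
                        max_jump: float = 0.05) -> PeakList:
    """Assign residue numbers to an unassigned list by nearest reference peak.

    Distances are measured in scaled (¹H, 0.2·¹⁵N) ppm coordinates; peaks
    farther than ``max_jump`` from every reference peak are dropped.  Greedy
    closest-first matching; each reference residue is used at most once.
    """
    ref = reference.peaks
    oth = other.peaks
    ref_xy = np.column_stack([ref["shift_H_ppm"], 0.2 * ref["shift_N_ppm"]])
    oth_xy = np.column_stack([oth["shift_H_ppm"], 0.2 * oth["shift_N_ppm"]])
    d = np.linalg.norm(ref_xy[:, None, :] - oth_xy[None, :, :], axis=2)
    rows = []
    used_ref: set[int] = set()
    used_oth: set[int] = set()
    for flat in np.argsort(d, axis=None):
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > max_jump:
            break
        if i in used_ref or j in used_oth:
            continue
        used_ref.add(int(i))
        used_oth.add(int(j))
        row = oth.iloc[int(j)].copy()
        row["residue"] = ref.iloc[int(i)]["residue"]
        rows.append(row)
    peaks = (pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)
             if rows else oth.iloc[0:0])
    return PeakList(other.titration_point, other.molar_ratio, peaks)


def csp_report(series: Sequence[PeakList],
               prolines: Sequence[int] = ()) -> list[ResidueCSP]:
    """Per-residue CSPs between the reference (first) and final points.

    ``prolines`` (and any residue listed there) have no backbone N–H and are
    emitted with the explicit ``missing`` marker, as are residues absent
    from either endpoint (e.g. broadened beyond detection).
    """
    if len(series) < 2:
        raise ValidationError("csp_report needs at least 2 titration points")
    tracks = track_peaks(series)
    out = []
    all_residues = sorted(set(tracks.residues) | set(int(p) for p in prolines))
    for r in all_residues:
        if r in prolines or r not in tracks.residues:
            out.append(ResidueCSP(r, math.nan, math.nan, math.nan,
                                  "missing", False))
            continue
        j = tracks.residues.index(r)
        h0, hn = tracks.shift_H[0, j], tracks.shift_H[-1, j]
        n0, nn = tracks.shift_N[0, j], tracks.shift_N[-1, j]
        broad = tracks.broadened(r)
        if math.isnan(h0) or math.isnan(hn):
            out.append(ResidueCSP(r, math.nan, math.nan, math.nan,
                                  "missing", broad))
            continue
        dh = hn - h0
        dn = nn - n0
        dav = csp_weighted_average(dh, dn)
        out.append(ResidueCSP(r, dh, dn, dav, classify_csp(dav), broad))
    return out


def per_point_csp(series: Sequence[PeakList]) -> pd.DataFrame:
    """δ_AV of every residue at every titration point relative to the
    reference; long-format DataFrame (point, ratio, residue, delta_av)."""
    if len(series) < 2:
        raise ValidationError("need at least 2 titration points")
    tracks = track_peaks(series)
    rows = []
    for i in range(1, len(series)):
        for j, r in enumerate(tracks.residues):
            dh = tracks.shift_H[i, j] - tracks.shift_H[0, j]
            dn = tracks.shift_N[i, j] - tracks.shift_N[0, j]
            dav = (csp_weighted_average(dh, dn)
                   if not (math.isnan(dh) or math.isnan(dn)) else math.nan)
            rows.append({"point": i, "ratio": tracks.ratios[i],
                         "residue": r, "delta_av": dav})
    return pd.DataFrame(rows)


def report_to_frame(report: Sequence[ResidueCSP]) -> pd.DataFrame:
    return pd.DataFrame([{
        "residue": r.residue_number, "dH": r.d_shift_H, "dN": r.d_shift_N,
        "delta_av": r.delta_av, "bin": r.bin, "broadened": r.broadened,
    } for r in report])
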