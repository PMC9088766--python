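"""Reaction coordinate, umbrella-window bookkeeping and WHAM free energies.

The hydride-transfer reaction coordinate is the distance difference

    ξ = d(H⁻, donor C) − d(H⁻, acceptor C9)      (Å)

which is negative in the reactant state (hydride on the nicotinamide) and
positive in the product.  Biased sampling in harmonic windows

    w_i(ξ) = ½ · k · (ξ − c_i)²                  (kcal/mol)

is recombined into the unbiased potential of mean force with the weighted
histogram analysis method (WHAM), iterating the window free-energy shifts
f_i to self-consistency:

    p(ξ_b) ∝ Σ_i H_i(ξ_b) / Σ_i N_i · exp([f_i − w_i(ξ_b)]/RT)
    f_i = −RT · ln Σ_b p(ξ_b) · exp(−w_i(ξ_b)/RT)

NOTE the bias convention: force constants are for ½k(ξ−c)²; inputs scored
as k(ξ−c)² (no ½) must be doubled before use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .errors import ConvergenceError, ValidationError
from .model_io import AtomId, Structure, WindowFile

UmbrellaWindow = WindowFile  # one type serves both I/O and analysis


@dataclass
class ReactionCoordinateSpec:
    donor_carbon: AtomId
    hydride: AtomId
    acceptor: AtomId

    def __post_init__(self) -> None:
        if len({self.donor_carbon, self.hydride, self.acceptor}) != 3:
            raise ValidationError("reaction coordinate needs three distinct atoms")


@dataclass
class PMF:
    """Reconstructed free-energy profile, minimum shifted to zero."""

    grid: np.ndarray          # bin centers, Å, strictly increasing
    free_energy: np.ndarray   # kcal/mol
    temperature: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.size != self.free_energy.size:
            raise ValidationError("grid/free_energy size mismatch")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")


def reaction_coordinate(frame: Structure, spec: ReactionCoordinateSpec) -> float:
    """ξ = d(hydride, donor carbon) − d(hydride, acceptor) in Å."""
    h = frame.get(spec.hydride).position
    x = float(np.linalg.norm(h - frame.get(spec.donor_carbon).position))
    y = float(np.linalg.norm(h - frame.get(spec.acceptor).position))
    return x - y


def window_ladder(start: float, stop: float, spacing: float) -> np.ndarray:
    """Arithmetic ladder of window centers, inclusive when commensurate.

    When (stop − start) is not an integer multiple of the spacing the ladder
    stops short of ``stop`` and a warning is emitted.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    if stop < start:
        raise ValidationError("stop must be >= start")
    span = stop - start
    n = int(math.floor(span / spacing + 1e-9))
    if abs(span - n * spacing) > 1e-9 * max(1.0, abs(span)):
        warnings.warn(
            f"window ladder endpoint {stop} dropped: span {span} is not a "
            f"multiple of spacing {spacing}", stacklevel=2)
    return start + spacing * np.arange(n + 1)


def wham_solve(windows: list[UmbrellaWindow],
               temperature: float = DEFAULT_TEMPERATURE,
               bin_width: float = 0.02, tol: float = 1e-6,
               max_iter: int = 100_000, mixing: float = 1.0) -> PMF:
    """Self-consistent WHAM combination of umbrella windows into a PMF.

    ``tol`` is the convergence threshold on the window shifts f_i
    (kcal/mol); ``mixing`` < 1 damps the f_i update if plain iteration
    oscillates.  Bins never visited by any window are dropped from the
    output grid.  Warns when adjacent windows' sample ranges do not overlap.
    """
    if not windows:
        raise ValidationError("wham_solve needs at least one window")
    for w in windows:
        if w.samples.size == 0:
            raise ValidationError("empty umbrella window")
    if temperature <= 0 or bin_width <= 0:
        raise ValidationError("temperature and bin_width must be > 0")
    rt = R_KCAL * temperature

    ordered = sorted(windows, key=lambda w: w.center)
    for lo, hi in zip(ordered, ordered[1:]):
        if lo.samples.max() < hi.samples.min():
            warnings.warn(
                f"no sample overlap between windows at {lo.center} and "
                f"{hi.center} Å; the profile may be disconnected", stacklevel=2)

    all_min = min(float(w.samples.min()) for w in windows)
    all_max = max(float(w.samples.max()) for w in windows)
    n_bins = max(1, int(math.ceil((all_max - all_min) / bin_width)))
    edges = all_min + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], all_max)  # keep the max sample inside
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_w = len(windows)
    counts = np.zeros((n_w, n_bins))
    n_i = np.zeros(n_w)
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
        n_i[i] = w.samples.size
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore"):
        log_total = np.log(total)

    # bias energies at bin centers: (n_windows, n_bins)
    bias = np.array([0.5 * w.force_constant * (centers - w.center) ** 2
                     for w in windows])
    log_n = np.log(n_i)

    f = np.zeros(n_w)
    for _ in range(max_iter):
        # log p (unnormalized), -inf at unvisited bins
        log_den = logsumexp(log_n[:, None] + (f[:, None] - bias) / rt, axis=0)
        log_p = log_total - log_den
        f_new = -rt * logsumexp(log_p[None, :] - bias / rt, axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = mixing * f_new + (1.0 - mixing) * f
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3e} kcal/mol)", residual=delta)

    log_den = logsumexp(log_n[:, None] + (f[:, None] - bias) / rt, axis=0)
    log_p = log_total - log_den
    visited = np.isfinite(log_p)
    log_p = log_p[visited] - logsumexp(log_p[visited])  # normalize: Σp = 1
    free = -rt * log_p
    free -= free.min()
    return PMF(centers[visited], free, temperature)


def unbiased_probability(pmf: PMF) -> np.ndarray:
    """Normalized bin probabilities implied by the PMF."""
    rt = R_KCAL * pmf.temperature
    p = np.exp(-pmf.free_energy / rt)
    return p / p.sum()


def barrier_height(pmf: PMF, reactant_range: tuple[float, float],
                   ts_range: tuple[float, float]) -> float:
    """max free energy over the TS range minus min over the reactant range."""
    def mask(rng: tuple[float, float]) -> np.ndarray:
        lo, hi = min(rng), max(rng)
        m = (pmf.grid >= lo) & (pmf.grid <= hi)
        if not m.any():
            raise ValidationError(f"range {rng} contains no PMF grid points")
        return m

    return float(pmf.free_energy[mask(ts_range)].max()
                 - pmf.free_energy[mask(reactant_range)].min())


def pmf_to_rows(pmf: PMF) -> list[tuple[float, float]]:
    """(ξ, free energy) rows for CSV output."""
    return list(zip(pmf.grid.tolist(), pmf.free_energy.tolist()))
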