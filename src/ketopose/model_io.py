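"""Readers/writers for structures, trajectories, umbrella windows and peak lists.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`AtomRecord` addressable by the ``(chain_id, residue_number,
atom_name)`` triple, and a :class:`Trajectory` is an ordered list of
structures sharing one atom roster.  Residue numbering is taken verbatim from
the input (author numbering is authoritative); no renumbering ever happens.

Supported formats
-----------------
* PDB (fixed-column ``ATOM``/``HETATM``; parsing via Biopython in strict
  mode).  Alternate locations are resolved to the highest-occupancy copy;
  insertion codes are rejected.
* multi-model PDB (``MODEL``/``ENDMDL``) and multi-frame XYZ for
  trajectories.  The XYZ dialect is: count line, comment line, then
  ``element x y z`` in Å.
* plain-text umbrella-window files: two header lines (``center``,
  ``force_constant``) followed by one reaction-coordinate sample per line.
* CSV peak lists with columns ``residue,shift_H_ppm,shift_N_ppm,intensity``.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AtomLookupError, IntegrityError, ParseError, ValidationError

AtomId = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


@dataclass
class AtomRecord:
    """One atom: identity plus Cartesian position in Å."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )
        if not self.atom_name:
            raise ValidationError("atom_name must be non-empty")
        if self.residue_number < 1:
            raise ValidationError(
                f"atom {self.atom_name}: residue_number must be >= 1 "
                f"(got {self.residue_number})"
            )

    @property
    def atom_id(self) -> AtomId:
        return (self.chain_id, self.residue_number, self.atom_name)


class Structure:
    """An ordered collection of atoms with unique (chain, resnum, name) triples."""

    def __init__(self, atoms: Iterable[AtomRecord], label: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.label = label
        self._index: dict[AtomId, int] = {}
        for i, a in enumerate(self.atoms):
            key = a.atom_id
            if key in self._index:
                raise IntegrityError(f"duplicate atom {key} in structure {label!r}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> AtomRecord:
        key = (chain_id, residue_number, atom_name)
        try:
            return self.atoms[self._index[key]]
        except KeyError:
            raise AtomLookupError(
                f"atom {atom_name} of residue {residue_number} chain {chain_id!r} "
                f"not found in structure {self.label!r}"
            ) from None

    def position(self, chain_id: str, residue_number: int, atom_name: str) -> np.ndarray:
        return self.atom(chain_id, residue_number, atom_name).position

    def get(self, atom_id: AtomId) -> AtomRecord:
        return self.atom(*atom_id)

    def select(self, *, atom_name: str | None = None, chain_id: str | None = None,
               residue_number: int | None = None,
               residue_name: str | None = None) -> list[AtomRecord]:
        """All atoms matching every given field (None matches anything)."""
        out = []
        for a in self.atoms:
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            out.append(a)
        return out

    def find_atom(self, residue_number: int, atom_name: str) -> AtomRecord:
        """Unique atom by (residue_number, atom_name) across all chains."""
        hits = self.select(atom_name=atom_name, residue_number=residue_number)
        if not hits:
            raise AtomLookupError(
                f"atom {atom_name} of residue {residue_number} not found "
                f"in structure {self.label!r}"
            )
        if len(hits) > 1:
            raise IntegrityError(
                f"atom {atom_name} of residue {residue_number} is ambiguous "
                f"({len(hits)} chains) in structure {self.label!r}"
            )
        return hits[0]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.atom_name, a.element, a.residue_name, a.residue_number,
                       a.chain_id, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, label if label is not None else self.label)

    def roster(self) -> tuple[AtomId, ...]:
        return tuple(a.atom_id for a in self.atoms)


class Trajectory:
    """Ordered frames sharing one atom roster."""

    def __init__(self, frames: Sequence[Structure], timestep: float = 1.0,
                 replica_id: str = "", site_id: str = ""):
        frames = list(frames)
        if not frames:
            raise ValidationError("trajectory needs at least one frame")
        if timestep <= 0:
            raise ValidationError("timestep must be positive")
        roster = frames[0].roster()
        for i, f in enumerate(frames[1:], start=1):
            if f.roster() != roster:
                raise IntegrityError(
                    f"frame {i} atom roster differs from frame 0 "
                    f"({len(f)} vs {len(frames[0])} atoms or reordered names)"
                )
        self.frames = frames
        self.timestep = float(timestep)
        self.replica_id = replica_id
        self.site_id = site_id

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]


@dataclass
class PeakList:
    """Assigned HSQC peaks at one titration point.

    ``peaks`` is a DataFrame with columns ``residue``, ``shift_H_ppm``,
    ``shift_N_ppm``, ``intensity``; at most one row per residue.
    """

    titration_point: int
    molar_ratio: float
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if self.molar_ratio < 0:
            raise ValidationError("molar_ratio must be >= 0")
        required = {"residue", "shift_H_ppm", "shift_N_ppm", "intensity"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValidationError(f"peak list missing columns: {sorted(missing)}")
        dup = self.peaks["residue"].duplicated()
        if dup.any():
            bad = sorted(self.peaks.loc[dup, "residue"].unique().tolist())
            raise IntegrityError(
                f"duplicate residues in peak list (point {self.titration_point}): {bad}"
            )


@dataclass
class WindowFile:
    """One umbrella-sampling window: bias parameters and ξ samples (Å)."""

    center: float
    force_constant: float  # kcal mol^-1 Å^-2, bias 1/2 k (xi - c)^2
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0 "
                                  "(zero means an unbiased window)")
        if self.samples.size == 0:
            raise ValidationError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("window samples must be finite")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _biopython_models(path: str | Path, label: str):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    text = Path(path).read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise ParseError(f"{path}: no ATOM/HETATM records")
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure(label, io.StringIO(text))
    except PDBConstructionException as exc:
        msg = str(exc)
        if "defined twice" in msg:
            raise IntegrityError(f"{path}: {msg}") from exc
        raise ParseError(f"{path}: {msg}") from exc
    except ValueError as exc:
        raise ParseError(f"{path}: malformed record ({exc})") from exc
    return structure


def _model_to_structure(model, label: str) -> Structure:
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if icode.strip():
                raise ParseError(
                    f"insertion code {icode!r} at residue {resseq} chain "
                    f"{chain.id!r}: insertion codes are not supported"
                )
            for atom in residue:
                if atom.is_disordered():
                    # resolve altlocs to the highest-occupancy copy
                    alt = max(atom.disordered_get_list(),
                              key=lambda a: (a.get_occupancy() or 0.0))
                else:
                    alt = atom
                atoms.append(AtomRecord(
                    atom_name=alt.get_name(),
                    element=(alt.element or "").strip() or alt.get_name()[0],
                    residue_name=residue.resname.strip(),
                    residue_number=int(resseq),
                    chain_id=chain.id,
                    position=np.asarray(alt.coord, dtype=float),
                ))
    return Structure(atoms, label)


def read_structure(path: str | Path, fmt: str = "pdb") -> Structure:
    """Read a single-frame structure (first model of a PDB file)."""
    if fmt != "pdb":
        raise ValidationError(f"unsupported structure format {fmt!r}")
    label = Path(path).stem
    bio = _biopython_models(path, label)
    models = list(bio)
    if not models:
        raise ParseError(f"{path}: no models found")
    return _model_to_structure(models[0], label)


def read_trajectory(path: str | Path, fmt: str = "pdb", timestep: float = 1.0,
                    replica_id: str = "", site_id: str = "") -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a trajectory."""
    label = Path(path).stem
    if fmt == "pdb":
        bio = _biopython_models(path, label)
        frames = [_model_to_structure(m, f"{label}_frame{i}")
                  for i, m in enumerate(bio)]
        if not frames:
            raise ParseError(f"{path}: no models found")
    elif fmt == "xyz":
        frames = _read_xyz_frames(path, label)
    else:
        raise ValidationError(f"unsupported trajectory format {fmt!r}")
    return Trajectory(frames, timestep=timestep, replica_id=replica_id,
                      site_id=site_id)


def _read_xyz_frames(path: str | Path, label: str) -> list[Structure]:
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path} line {i + 1}: expected atom count") from None
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise ParseError(f"{path} line {i + 1}: truncated frame ({n} atoms)")
        atoms = []
        for j in range(n):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path} line {ln + 1}: expected 'element x y z'")
            el = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path} line {ln + 1}: non-numeric coordinate"
                ) from None
            atoms.append(AtomRecord(
                atom_name=el, element=el, residue_name="XYZ",
                residue_number=j + 1, chain_id="X", position=np.array(xyz),
            ))
        frames.append(Structure(atoms, f"{label}_frame{len(frames)}"))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def _format_pdb_atom(serial: int, a: AtomRecord) -> str:
    name = a.atom_name
    if len(name) < 4:
        name = f" {name:<3s}"
    x, y, z = a.position
    return (f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element[:2]:>2s}")


def write_structure(s: Structure, path: str | Path) -> None:
    lines = [_format_pdb_atom(i + 1, a) for i, a in enumerate(s.atoms)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str = "pdb") -> None:
    if fmt == "pdb":
        lines: list[str] = []
        for m, frame in enumerate(traj.frames, start=1):
            lines.append(f"MODEL     {m:4d}")
            lines.extend(_format_pdb_atom(i + 1, a)
                         for i, a in enumerate(frame.atoms))
            lines.append("ENDMDL")
        lines.append("END")
    elif fmt == "xyz":
        lines = []
        for frame in traj.frames:
            lines.append(str(len(frame)))
            lines.append(frame.label or "frame")
            for a in frame:
                x, y, z = a.position
                lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    else:
        raise ValidationError(f"unsupported trajectory format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Umbrella-window files
# ---------------------------------------------------------------------------

def read_window_file(path: str | Path) -> WindowFile:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header: dict[str, float] = {}
    body_start = 0
    for ln in lines[:2]:
        parts = ln.split()
        if len(parts) == 2 and parts[0] in ("center", "force_constant"):
            try:
                header[parts[0]] = float(parts[1])
            except ValueError:
                raise ParseError(f"{path}: non-numeric header value in {ln!r}") from None
            body_start += 1
    if "center" not in header or "force_constant" not in header:
        raise ParseError(
            f"{path}: expected 'center <Å>' and 'force_constant <kcal/mol/Å²>' headers"
        )
    samples = []
    for i, ln in enumerate(lines[body_start:]):
        try:
            samples.append(float(ln.split()[-1]))
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric sample {ln!r} (line {body_start + i + 1})"
            ) from None
    return WindowFile(header["center"], header["force_constant"], np.array(samples))


def write_window_file(w: WindowFile, path: str | Path) -> None:
    lines = [f"center {w.center:.10g}", f"force_constant {w.force_constant:.10g}"]
    lines.extend(f"{x:.10g}" for x in w.samples)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def read_peaklist_csv(path: str | Path, titration_point: int,
                      molar_ratio: float) -> PeakList:
    df = pd.read_csv(path)
    df = df.rename(columns=str.strip)
    return PeakList(titration_point, molar_ratio, df)


def write_peaklist_csv(pl: PeakList, path: str | Path) -> None:
    pl.peaks.to_csv(path, index=False)


def read_titration_manifest(path: str | Path) -> list[PeakList]:
    """Manifest CSV with columns ``point,ratio,file``; paths relative to it."""
    mdir = Path(path).parent
    manifest = pd.read_csv(path)
    out = []
    for _, row in manifest.iterrows():
        out.append(read_peaklist_csv(mdir / str(row["file"]), int(row["point"]),
                                     float(row["ratio"])))
    return out
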