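import numpy as np
import pytest

from ketopose.model_io import AtomRecord, Structure


def make_structure(atoms: dict, label: str = "fixture") -> Structure:
    """Build a Structure from {(chain, resnum, name): (x, y, z)}.

    Element is inferred from the first letter of the atom name.
    """
    records = []
    for (chain, resnum, name), pos in atoms.items():
        records.append(AtomRecord(
            atom_name=name, element=name[0], residue_name="UNK",
            residue_number=resnum, chain_id=chain,
            position=np.asarray(pos, dtype=float)))
    return Structure(records, label)


@pytest.fixture
def carbonyl_frame():
    """Trigonal C9 carbonyl with the hydride on the Re face (pro-S side).

    C9 at the origin, O9 on +x, C8/C10 trigonal in the xy-plane; with
    priorities O9 > C8 > C10 the normal (O9-C9)x(C8-C9) points +z, so the
    Re face is the -z side.
    """
    return make_structure({
        ("S", 2, "C9"): (0.0, 0.0, 0.0),
        ("S", 2, "O9"): (1.23, 0.0, 0.0),
        ("S", 2, "C8"): (-0.755, 1.308, 0.0),
        ("S", 2, "C10"): (-0.755, -1.308, 0.0),
        ("N", 1, "H4N"): (0.0, 0.0, -2.7),
        ("N", 1, "C4N"): (0.0, 0.0, -3.8),
    })


def random_rigid_motion(rng):
    """A uniformly random (rotation, translation) pair."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    trans = rng.normal(0.0, 10.0, size=3)
    return rot, trans


def apply_rigid(structure: Structure, rot, trans) -> Structure:
    return structure.with_coords(rot.apply(structure.coords) + trans)


def mirror(structure: Structure, axis: int = 2) -> Structure:
    coords = structure.coords.copy()
    coords[:, axis] *= -1.0
    return structure.with_coords(coords)
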