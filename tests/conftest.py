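import numpy as np
import pytest

from chromkit.core_io import Atom, StructureFrame, Trajectory
from chromkit import core_io, geometry


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00      PROA N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00      PROA C
ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.00      PROA C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def toy_protein():
    """4-residue CA/CB toy protein topology."""
    atoms = []
    coords = []
    for resid in range(1, 5):
        for name in ("CA", "CB"):
            atoms.append(Atom(name, "C", resid, "ALA", "PROA"))
            coords.append([float(resid), 1.0 if name == "CB" else 0.0, 0.0])
    return StructureFrame(atoms, np.array(coords))


def make_trajectory(frames, names=None, elements=None, resids=None, segids=None):
    """Build a Trajectory from a (n_frames, n_atoms, 3) array with labels."""
    frames = np.asarray(frames, float)
    n_atoms = frames.shape[1]
    atoms = [
        Atom(
            (names or ["X"] * n_atoms)[i],
            (elements or ["C"] * n_atoms)[i],
            (resids or list(range(1, n_atoms + 1)))[i],
            "UNK",
            (segids or ["A"] * n_atoms)[i],
        )
        for i in range(n_atoms)
    ]
    return Trajectory(StructureFrame(atoms, frames[0]), frames)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def plane_spec_from_truth(topology, truth):
    sels = truth["selections"]
    return geometry.PlaneSpec(
        quadrant_a=core_io.resolve_selection(topology, sels["quadrant_a"]),
        quadrant_b=core_io.resolve_selection(topology, sels["quadrant_b"]),
        dyad_pair=core_io.resolve_selection(topology, sels["dyad_pair"]),
        core_reference=core_io.resolve_selection(topology, sels["core_reference"]),
    )


def arm_spec_from_truth(topology, truth, side):
    sels = truth["selections"]
    return geometry.LinkerArmSpec(
        core_io.resolve_selection(topology, sels[f"{side}_origin"]),
        core_io.resolve_selection(topology, sels[f"{side}_terminal"]),
        side=side,
    )
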