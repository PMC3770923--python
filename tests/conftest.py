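import warnings

import numpy as np
import pytest

import tcrforge as tf
from tcrforge.fixtures import _build_residue_atoms, _orient_residue
from tcrforge.structmodel import (ParameterizedStructure, ResidueInfo,
                                  assign_parameters, split_partners)
from tcrforge.templates import TEMPLATES

warnings.filterwarnings("ignore", message=".*not alanine-mutable.*")


@pytest.fixture(scope="session")
def toy():
    """Default toy complex with its truth record."""
    return tf.make_toy_complex()


@pytest.fixture(scope="session")
def toy5():
    """Five-frame toy complex (jittered frames)."""
    return tf.make_toy_complex(n_frames=5)


def point_structure(positions, charges, born=3.0, rmin2=2.0, eps=0.1,
                    n_receptor=None, n_frames=1):
    """Minimal parameterized structure of free point 'atoms', one per
    residue; the first ``n_receptor`` go to chain R, the rest to chain L."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n_receptor is None:
        n_receptor = n
    residues = [ResidueInfo("R" if i < n_receptor else "L", i + 1, " ", "XXX")
                for i in range(n)]
    as_arr = lambda v: np.full(n, v, dtype=float) if np.isscalar(v) \
        else np.asarray(v, dtype=float)
    frames = np.repeat(positions[None, :, :], n_frames, axis=0)
    return ParameterizedStructure(
        atom_names=["X"] * n, elements=["C"] * n,
        res_index=np.arange(n), frames=frames, residues=residues,
        charges=as_arr(charges), rmin2=as_arr(rmin2), eps=as_arr(eps),
        born=as_arr(born),
        partner_of=np.array([1 if i < n_receptor else 2 for i in range(n)]))


def mini_pair(rec_name, lig_name, separation=12.0):
    """Two full residues facing each other: receptor (chain R) above,
    ligand (chain L) below; parameterized and partner-split."""
    names, elements, residx, coords, residues = [], [], [], [], []
    for k, (resname, ca, side) in enumerate([
            (lig_name, np.zeros(3), np.array([0.0, 0.0, 1.0])),
            (rec_name, np.array([0.0, 0.0, separation]),
             np.array([0.0, 0.0, -1.0]))]):
        placed = _orient_residue(_build_residue_atoms(resname), ca, side,
                                 np.array([1.0, 0.0, 0.0]))
        residues.append(ResidueInfo("L" if k == 0 else "R", 1, " ", resname))
        for aname, pos in placed.items():
            names.append(aname)
            elements.append(TEMPLATES[resname].atoms[aname].element)
            residx.append(k)
            coords.append(pos)
    s = ParameterizedStructure(
        atom_names=names, elements=elements,
        res_index=np.asarray(residx), frames=np.asarray(coords)[None, :, :],
        residues=residues)
    s = assign_parameters(s)
    return split_partners(s, ["R"], ["L"])
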