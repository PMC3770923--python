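import numpy as np
import pytest

import tcrforge as tf
from conftest import mini_pair
from tcrforge.fixtures import (LIGAND_CHAINS, RECEPTOR_CHAINS, ToyComplexSpec,
                               region_map_for, write_toy_complex)
from tcrforge.structmodel import (MutationError, ParameterizationError,
                                  RegionMap, StructureError,
                                  assign_parameters, build_alanine_mutant,
                                  build_point_mutant, read_structure,
                                  split_partners, tag_regions,
                                  write_structure)
from tcrforge.templates import TEMPLATES, ParameterTable


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip_preserves_topology_and_coordinates(tmp_path, toy):
    s, _ = toy
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_structure(s, p1)
    r1 = read_structure(p1)
    write_structure(r1, p2)
    r2 = read_structure(p2)
    assert r1.n_atoms == s.n_atoms == r2.n_atoms
    assert r1.atom_names == r2.atom_names
    assert np.abs(r1.frames - s.frames[:1]).max() < 1e-3
    assert np.abs(r2.frames - r1.frames).max() < 1e-3


def test_multi_model_read_policies(tmp_path, toy5):
    s, _ = toy5
    p = tmp_path / "m.pdb"
    write_structure(s, p)
    all_frames = read_structure(p, frame_policy="all")
    first = read_structure(p, frame_policy="first")
    assert all_frames.n_frames == 5
    assert first.n_frames == 1
    # identical atom ordering across models
    assert all_frames.atom_names == first.atom_names


def test_inconsistent_models_rejected(tmp_path, toy5):
    s, _ = toy5
    p = tmp_path / "m.pdb"
    write_structure(s, p)
    lines = p.read_text().splitlines(keepends=True)
    # remove one ATOM record from the second model
    model2 = next(i for i, l in enumerate(lines) if l.startswith("MODEL") and
                  "2" in l.split())
    atom_line = next(i for i in range(model2, len(lines))
                     if lines[i].startswith("ATOM"))
    del lines[atom_line]
    p.write_text("".join(lines))
    with pytest.raises(StructureError, match="inconsistent"):
        read_structure(p, frame_policy="all")


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def test_template_charges_sum_to_formal_charge():
    for name, tmpl in TEMPLATES.items():
        total = sum(p.charge for p in tmpl.atoms.values())
        assert abs(total - tmpl.formal_charge) < 1e-4, name


def test_assign_parameters_is_idempotent(toy):
    s, _ = toy
    again = assign_parameters(s)
    assert again.atom_names == s.atom_names
    assert np.allclose(again.charges, s.charges)
    assert np.abs(again.frames - s.frames).max() < 1e-12


def test_polar_hydrogens_built_for_bare_heavy_atoms(tmp_path, toy):
    s, _ = toy
    # strip all hydrogens, write, re-read, re-parameterize
    import copy
    mask = np.array([e != "H" for e in s.elements])
    from tcrforge.structmodel import _apply_atom_mask
    bare = _apply_atom_mask(s, mask)
    p = tmp_path / "noh.pdb"
    write_structure(bare, p)
    rebuilt = assign_parameters(read_structure(p))
    assert rebuilt.n_atoms == s.n_atoms
    # rebuilt H sit at ~1 A from their heavy partner
    ri = rebuilt.residue_index_of(("D", 26))  # LYS
    nz = rebuilt.atom_index(ri, "NZ")
    hz = rebuilt.atom_index(ri, "HZ1")
    d = np.linalg.norm(rebuilt.coords[nz] - rebuilt.coords[hz])
    assert 0.9 < d < 1.1


def test_unknown_residue_policy(tmp_path, toy):
    s, _ = toy
    p = tmp_path / "bad.pdb"
    write_structure(s, p)
    txt = p.read_text().replace("LYS", "XYZ")
    p.write_text(txt)
    raw = read_structure(p)
    with pytest.raises(ParameterizationError, match="XYZ"):
        assign_parameters(raw, unknown_policy="error")
    with pytest.warns(UserWarning, match="skipped"):
        ok = assign_parameters(raw, unknown_policy="skip-residue")
    assert ok.skipped_residues
    assert all(r.name != "XYZ" for r in ok.residues)


# ---------------------------------------------------------------------------
# Partner split / regions
# ---------------------------------------------------------------------------

def test_split_partners_records_and_validates(toy):
    s, _ = toy
    again = split_partners(s, RECEPTOR_CHAINS, LIGAND_CHAINS)
    assert set(again.partner_of) == {1, 2}
    with pytest.raises(StructureError, match="overlap"):
        split_partners(s, ["D"], ["D"])
    with pytest.raises(StructureError, match="missing"):
        split_partners(s, ["D", "E"], ["Z"])


def test_tag_regions_defaults_and_errors(toy):
    s, _ = toy
    tagged = tag_regions(s, region_map_for(ToyComplexSpec()))
    regions = {r.label: r.region for r in tagged.residues}
    assert regions["D:LYS26"] == "CDR1a"
    assert regions["D:ALA10"] == "framework"   # untouched receptor default
    assert regions["C:GLU1"] == "MHC"
    with pytest.raises(StructureError, match="outside"):
        tag_regions(s, RegionMap([("D", 900, 999, "CDR1a")]))


# ---------------------------------------------------------------------------
# Mutant builders
# ---------------------------------------------------------------------------

def test_alanine_mutant_truncates_and_freezes_backbone(toy5):
    s, _ = toy5
    ri = s.residue_index_of(("D", 26))
    mut = build_alanine_mutant(s, ("D", 26))
    assert mut.residues[ri].name == "ALA"
    lys_side = len(TEMPLATES["LYS"].atoms) - len(TEMPLATES["ALA"].atoms)
    assert s.n_atoms - mut.n_atoms == lys_side
    for name in ("N", "H", "CA", "C", "O", "CB"):
        i1, i2 = s.atom_index(ri, name), mut.atom_index(ri, name)
        assert np.array_equal(s.frames[:, i1], mut.frames[:, i2])
    # charge retyped to ALA (net 0)
    q = mut.charges[mut.atom_indices_of_residue(ri)].sum()
    assert abs(q) < 1e-4


def test_alanine_mutant_identity_and_errors(toy):
    s, _ = toy
    same = build_alanine_mutant(s, ("D", 10))  # already ALA
    assert same.n_atoms == s.n_atoms
    assert np.array_equal(same.frames, s.frames)
    gly = build_point_mutant(s, ("D", 11), "GLY")
    with pytest.raises(MutationError, match="GLY"):
        build_alanine_mutant(gly, ("D", 11))
    pro = build_point_mutant(s, ("D", 12), "PRO")
    with pytest.raises(MutationError, match="PRO"):
        build_alanine_mutant(pro, ("D", 12))


def test_point_mutant_identity_is_exact(toy):
    s, _ = toy
    same = build_point_mutant(s, ("D", 26), "LYS")
    assert same.atom_names == s.atom_names
    assert np.array_equal(same.frames, s.frames)


def test_point_mutant_ala_to_glu_geometry():
    """A -> E at an exposed site: 4 extra heavy atoms placed at ideal bond
    lengths, no clash, backbone untouched."""
    s = mini_pair("ALA", "SER", separation=14.0)
    mut = build_point_mutant(s, ("R", 1), "GLU")
    ri = mut.residue_index_of(("R", 1))
    heavy = lambda st: sum(1 for i in st.atom_indices_of_residue(
        st.residue_index_of(("R", 1))) if st.elements[i] != "H")
    assert heavy(mut) - heavy(s) == 4
    for name in ("N", "CA", "C", "O", "CB"):
        i1 = s.atom_index(s.residue_index_of(("R", 1)), name)
        i2 = mut.atom_index(ri, name)
        assert np.allclose(s.coords[i1], mut.coords[i2])
    # hand-checked internal geometry: CB-CG bond 1.52, CD-OE1 1.25
    cb, cg = mut.atom_index(ri, "CB"), mut.atom_index(ri, "CG")
    cd, oe1 = mut.atom_index(ri, "CD"), mut.atom_index(ri, "OE1")
    assert abs(np.linalg.norm(mut.coords[cb] - mut.coords[cg]) - 1.52) < 1e-6
    assert abs(np.linalg.norm(mut.coords[cd] - mut.coords[oe1]) - 1.25) < 1e-6


def test_point_mutant_clash_error_in_buried_pocket():
    """Growing a long side-chain into a deliberately packed cage fails with
    a clash report."""
    s = mini_pair("ALA", "TRP", separation=6.0)  # receptor ALA very close
    with pytest.raises(MutationError, match="clash"):
        build_point_mutant(s, ("R", 1), "ARG")


def test_double_alanine_application_is_noop(toy):
    s, _ = toy
    once = build_alanine_mutant(s, ("E", 50))
    twice = build_alanine_mutant(once, ("E", 50))
    assert np.array_equal(once.frames, twice.frames)
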