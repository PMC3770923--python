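import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcrforge as tf
from conftest import point_structure
from tcrforge.constants import COULOMB_KCAL
from tcrforge.energetics import (DielectricModel, EnergyBreakdown, EnergyError,
                                 NonpolarParams, binding_energy,
                                 effective_energy, gb_energy,
                                 hct_effective_radii, pair_elec, pair_vdw,
                                 sasa, sasa_per_atom)
from tcrforge.geometry import rotation_about_axis

TAU = 1.0 - 1.0 / 78.5


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

def test_coulomb_unit_charges_at_reference_distance():
    """Two +1e charges 3.320637 A apart in eps_in=1 give exactly +100."""
    s = point_structure([[0, 0, 0], [3.320637, 0, 0]], [1.0, 1.0],
                        n_receptor=1)
    assert pair_elec(s, "receptor", "ligand") == pytest.approx(100.0, abs=1e-4)


def test_coulomb_empty_group_is_zero(toy):
    s, _ = toy
    assert pair_elec(s, "receptor", np.zeros(s.n_atoms, dtype=bool)) == 0.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(q=st.floats(0.1, 2.0), r=st.floats(2.0, 30.0))
def test_coulomb_antisymmetric_under_charge_flip(q, r):
    s1 = point_structure([[0, 0, 0], [r, 0, 0]], [q, q], n_receptor=1)
    s2 = point_structure([[0, 0, 0], [r, 0, 0]], [q, -q], n_receptor=1)
    e1 = pair_elec(s1, "receptor", "ligand")
    e2 = pair_elec(s2, "receptor", "ligand")
    assert e2 == pytest.approx(-e1, rel=1e-12)


def test_coulomb_overlapping_atoms_error():
    s = point_structure([[0, 0, 0], [0, 0, 0]], [1.0, 1.0], n_receptor=1)
    with pytest.raises(EnergyError, match="overlap"):
        pair_elec(s, "receptor", "ligand")


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

def test_lj_minimum_depth_at_contact():
    """Two identical atoms at r = rmin_i + rmin_j sit at -eps_pair."""
    s = point_structure([[0, 0, 0], [4.0, 0, 0]], 0.0, rmin2=2.0, eps=0.25,
                        n_receptor=1)
    assert pair_vdw(s, "receptor", "ligand") == pytest.approx(-0.25, rel=1e-12)


def test_lj_decays_at_long_range():
    s = point_structure([[0, 0, 0], [50.0, 0, 0]], 0.0, n_receptor=1)
    assert abs(pair_vdw(s, "receptor", "ligand")) < 1e-6


def test_lj_matches_brute_force_pair_enumeration():
    rng = np.random.default_rng(4)
    pos = rng.uniform(0, 8, size=(5, 3))
    rmin2 = rng.uniform(1.5, 2.2, 5)
    eps = rng.uniform(0.05, 0.4, 5)
    s = point_structure(pos, 0.0, rmin2=rmin2, eps=eps, n_receptor=2)
    expected = 0.0
    for i in range(2):
        for j in range(2, 5):
            r = np.linalg.norm(pos[i] - pos[j])
            rm = rmin2[i] + rmin2[j]
            e = np.sqrt(eps[i] * eps[j])
            expected += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
    assert pair_vdw(s, "receptor", "ligand") == pytest.approx(expected,
                                                              abs=1e-12)


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def test_gb_single_ion_equals_born_formula():
    s = point_structure([[0, 0, 0]], 1.0, born=3.0)
    expected = -0.5 * COULOMB_KCAL * TAU / 3.0      # ~ -54.64 kcal/mol
    assert gb_energy(s) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(-54.639, abs=1e-3)


def test_gb_zero_charges_zero_energy(toy):
    s, _ = toy
    s0 = s.copy()
    s0.charges = np.zeros_like(s.charges)
    assert gb_energy(s0) == 0.0


def test_gb_two_ions_match_hand_evaluated_descreening():
    """Closed-form oracle: the descreening integral and the GB interpolation
    evaluated with scalar arithmetic for two ions at 50 A."""
    r, rho, scale, q = 50.0, 3.0, 0.8, 1.0
    sj = scale * rho
    L, U = max(abs(r - sj), rho), r + sj
    term = (1 / L - 1 / U) + 0.25 * (r - sj * sj / r) * (1 / U**2 - 1 / L**2) \
        + 0.5 * np.log(L / U) / r
    inv_a = 1 / rho - 0.5 * term
    a = 1 / inv_a
    f = np.sqrt(r * r + a * a * np.exp(-r * r / (4 * a * a)))
    expected = -0.5 * COULOMB_KCAL * TAU * (2 * q * q / a + 2 * q * q / f)
    s = point_structure([[0, 0, 0], [50.0, 0, 0]], 1.0, born=3.0)
    assert gb_energy(s) == pytest.approx(expected, abs=1e-6)


def test_gb_vanishes_when_solvent_matches_solute_dielectric():
    s = point_structure([[0, 0, 0], [5.0, 0, 0]], 1.0, born=3.0)
    d = DielectricModel(eps_in=1.0, eps_out=1.0 + 1e-9)
    assert abs(gb_energy(s, None, d)) < 1e-6


def test_effective_radii_grow_with_burial():
    rng = np.random.default_rng(1)
    xyz = rng.uniform(-3, 3, size=(20, 3))
    rho = np.full(20, 1.8)
    a = hct_effective_radii(xyz, rho)
    assert np.all(a >= rho - 1e-12)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_atom_closed_form():
    area = sasa_per_atom(np.zeros((1, 3)), np.array([1.9]), 1.4)
    exact = 4 * np.pi * 3.3 ** 2
    assert area[0] == pytest.approx(exact, rel=5e-3)


def test_sasa_fully_buried_atom_is_zero():
    # central atom caged by 26 tightly packed neighbours
    offsets = [np.array([i, j, k], dtype=float)
               for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    xyz = np.vstack([[0, 0, 0], 2.2 * np.array(offsets)])
    radii = np.full(len(xyz), 1.9)
    per = sasa_per_atom(xyz, radii, 1.4)
    assert per[0] == 0.0
    assert np.all(per >= 0)


def test_sasa_two_atom_overlap_matches_spherical_cap_formula():
    """Analytic two-sphere oracle: exposed area of each sphere is
    4 pi R^2 - 2 pi R h with cap height h from the intersection plane."""
    r1, r2, probe, d = 1.9, 1.7, 1.4, 2.5
    R1, R2 = r1 + probe, r2 + probe
    per = sasa_per_atom(np.array([[0, 0, 0], [d, 0, 0]]),
                        np.array([r1, r2]), probe)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    exact = np.array([4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1,
                      4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2])
    assert np.allclose(per, exact, rtol=1e-2)


def test_sasa_per_atom_sums_to_total(toy):
    s, _ = toy
    total, per = sasa(s, "receptor")
    assert np.all(per >= 0)
    assert total == pytest.approx(per.sum(), abs=1e-9)


# ---------------------------------------------------------------------------
# Effective and binding energies
# ---------------------------------------------------------------------------

def test_breakdown_total_is_exact_sum(toy):
    s, _ = toy
    e = effective_energy(s)
    assert e.total == pytest.approx(e.elec + e.vdw + e.gb + e.np, abs=1e-9)


def test_separated_neutral_partners_have_no_interaction():
    """Two neutral dipoles 500 A apart: the cross terms vanish."""
    pos = [[0, 0, 0], [2, 0, 0], [0, 0, 500], [2, 0, 500]]
    s = point_structure(pos, [0.5, -0.5, 0.8, -0.8], n_receptor=2)
    e = effective_energy(s)
    assert abs(e.elec) < 1e-3
    assert abs(e.vdw) < 1e-3


def test_separated_complex_has_no_binding_energy(toy):
    s, _ = toy
    far = s.copy()
    far.frames = far.frames.copy()
    far.frames[:, far.receptor_mask, :] += np.array([0.0, 0.0, 500.0])
    b = binding_energy(far)
    assert abs(b.total) < 0.05


def test_binding_energy_invariant_under_rigid_transform(toy):
    s, _ = toy
    moved = s.copy()
    R = rotation_about_axis([0.2, -0.7, 0.4], 123.0)
    moved.frames = s.frames @ R.T + np.array([5.0, -3.0, 11.0])
    e1, e2 = binding_energy(s), binding_energy(moved)
    for k in ("elec", "vdw", "gb", "np"):
        assert getattr(e1, k) == pytest.approx(getattr(e2, k), abs=1e-6)


def test_binding_gas_terms_equal_inter_partner_pair_sums(toy5):
    """The single-trajectory identity: delta-elec/vdw reduce exactly to the
    cross-partner pair sums."""
    s, _ = toy5
    b = binding_energy(s)
    assert b.elec == pytest.approx(pair_elec(s, "receptor", "ligand"),
                                   abs=1e-12)
    assert b.vdw == pytest.approx(pair_vdw(s, "receptor", "ligand"),
                                  abs=1e-12)
    assert b.intra == 0.0


def test_salt_bridge_complex_binds_electrostatically(toy):
    s, truth = toy
    b = binding_energy(s)
    assert b.elec < 0  # engineered salt bridges attract
    assert truth["hotspots"]


def test_dielectric_and_nonpolar_validation():
    with pytest.raises(ValueError):
        DielectricModel(eps_in=80.0, eps_out=1.0)
    with pytest.raises(ValueError):
        NonpolarParams(gamma=-0.1)
    with pytest.raises(ValueError):
        NonpolarParams(probe_radius=0.0)
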