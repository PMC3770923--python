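import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcrforge as tf
from conftest import point_structure
from tcrforge.geometry import angular_shift, rotation_about_axis
from tcrforge.orientation import (OrientationLandscape, find_minimum,
                                  rigid_scan, subgroup_contributions,
                                  tcr_axis)
from tcrforge.structmodel import StructureError


def _prolate_cloud(n_receptor=40):
    rng = np.random.default_rng(0)
    rec = rng.normal(0, 1, (n_receptor, 3)) * np.array([6.0, 1.0, 1.0])
    lig = rng.normal(0, 1, (10, 3)) + np.array([25.0, 0.0, 0.0])
    return np.vstack([rec, lig]), n_receptor


# ---------------------------------------------------------------------------
# Principal axis
# ---------------------------------------------------------------------------

def test_axis_of_prolate_cloud_points_at_ligand():
    pos, nr = _prolate_cloud()
    s = point_structure(pos, 0.1, n_receptor=nr)
    axis, anchor = tcr_axis(s)
    assert abs(abs(axis[0]) - 1.0) < 1e-2
    assert axis[0] > 0   # sign toward the ligand at +x
    assert np.allclose(anchor, pos[:nr].mean(axis=0))


def test_axis_is_equivariant_under_rotation():
    pos, nr = _prolate_cloud()
    s1 = point_structure(pos, 0.1, n_receptor=nr)
    a1, _ = tcr_axis(s1)
    R = rotation_about_axis([1.0, 2.0, -0.5], 73.0)
    s2 = point_structure(pos @ R.T, 0.1, n_receptor=nr)
    a2, _ = tcr_axis(s2)
    assert np.allclose(a2, R @ a1, atol=1e-6)


def test_axis_degenerate_cube_lattice_errors():
    grid = np.array([[i, j, k] for i in range(4) for j in range(4)
                     for k in range(4)], dtype=float) * 3.0
    pos = np.vstack([grid, grid + np.array([30.0, 0, 0])])
    s = point_structure(pos, 0.1, n_receptor=len(grid))
    with pytest.raises(StructureError, match="degenerate"):
        tcr_axis(s)


# ---------------------------------------------------------------------------
# Rigid scan
# ---------------------------------------------------------------------------

def test_default_grid_covers_protocol(toy):
    s, _ = toy
    ls = rigid_scan(s, angle_step=45.0)     # coarse angles, default distances
    assert np.allclose(ls.distances, [6.0, 8.0, 10.0, 12.0])
    ls5 = rigid_scan(s, d_min=8, d_max=8, d_step=1.0)
    assert len(ls5.angles) == 72            # every 5 degrees, no 360 duplicate
    assert ls5.angles[0] == 0.0 and ls5.angles[-1] == 355.0


def test_scan_is_deterministic(toy):
    s, _ = toy
    l1 = rigid_scan(s, d_min=8, d_max=8, d_step=1, angle_step=60.0)
    l2 = rigid_scan(s, d_min=8, d_max=8, d_step=1, angle_step=60.0)
    assert np.array_equal(l1.energy, l2.energy)


def test_landscape_invariant_under_global_rigid_transform(toy):
    s, _ = toy
    moved = s.copy()
    R = rotation_about_axis([0.5, 0.5, -0.1], 64.0)
    moved.frames = s.frames @ R.T + np.array([7.0, 1.0, -4.0])
    l1 = rigid_scan(s, d_min=8, d_max=8, d_step=1, angle_step=45.0)
    l2 = rigid_scan(moved, d_min=8, d_max=8, d_step=1, angle_step=45.0)
    assert np.abs(l1.energy - l2.energy).max() < 1e-6


def test_minimum_matches_fine_reference_scan(toy):
    """Oracle identity: the 5-degree minimum lies within one step of the
    1-degree exhaustive reference minimum."""
    s, truth = toy
    coarse = find_minimum(rigid_scan(s, d_min=8, d_max=8, d_step=1))
    fine = find_minimum(rigid_scan(s, d_min=8, d_max=8, d_step=1,
                                   angle_step=1.0))
    assert angular_shift(coarse[1], fine[1]) <= 5.0
    assert angular_shift(coarse[1], truth["native_angle"]) <= 5.0


def test_polar_mode_agrees_with_full_mode_on_locked_fixture(toy):
    """Dropping the vdW term does not move the located minimum on an
    electrostatically locked complex."""
    s, _ = toy
    polar = find_minimum(rigid_scan(s, d_min=8, d_max=8, d_step=1,
                                    energy_mode="polar"))
    full = find_minimum(rigid_scan(s, d_min=8, d_max=8, d_step=1,
                                   energy_mode="full"))
    assert angular_shift(polar[1], full[1]) <= 5.0


# ---------------------------------------------------------------------------
# Minimum search
# ---------------------------------------------------------------------------

def _landscape(energy, distances=None, angles=None):
    energy = np.atleast_2d(np.asarray(energy, dtype=float))
    nd, na = energy.shape
    return OrientationLandscape(
        distances=np.asarray(distances if distances is not None
                             else np.arange(nd) + 6.0, dtype=float),
        angles=np.asarray(angles if angles is not None
                          else np.arange(na) * (360.0 / na), dtype=float),
        energy=energy, flagged=np.zeros_like(energy, dtype=bool),
        energy_mode="polar")


def test_constant_landscape_tie_breaks_to_origin():
    ls = _landscape(np.zeros((3, 8)))
    d, a, e, margin = find_minimum(ls)
    assert (d, a) == (6.0, 0.0)
    assert margin == 0.0


def test_cosine_landscape_minimum_at_antipode():
    angles = np.arange(0.0, 360.0, 5.0)
    ls = _landscape(np.cos(np.radians(angles))[None, :], angles=angles)
    d, a, e, margin = find_minimum(ls)
    assert a == 180.0
    assert e == pytest.approx(-1.0)


def test_two_basin_margin_reported():
    angles = np.arange(0.0, 360.0, 5.0)
    e = np.cos(np.radians(angles)) + 0.5 * np.cos(np.radians(2 * angles + 60))
    ls = _landscape(e[None, :], angles=angles)
    d, a, emin, margin = find_minimum(ls)
    assert margin > 0


def test_all_flagged_errors():
    ls = _landscape(np.zeros((1, 4)))
    ls.flagged[:] = True
    with pytest.raises(ValueError, match="flagged"):
        find_minimum(ls)


# ---------------------------------------------------------------------------
# Subgroup decomposition
# ---------------------------------------------------------------------------

def test_group_profiles_sum_to_total(toy):
    s, _ = toy
    profs, total = subgroup_contributions(s, distance=8.0, angle_step=30.0)
    stacked = np.sum([p.energy for p in profs], axis=0)
    assert np.abs(stacked - total.energy).max() < 1e-6


def test_charged_cdr12_group_carries_the_signal(toy):
    s, _ = toy
    profs, _ = subgroup_contributions(s, distance=8.0, angle_step=15.0)
    shares = {p.label: p.share for p in profs}
    assert shares["CDR1,2/MHC"] > 0.9
    assert shares["framework"] < 0.05


def test_uncharged_group_profile_is_flat(toy):
    s, _ = toy
    profs, _ = subgroup_contributions(s, distance=8.0, angle_step=30.0)
    fw = next(p for p in profs if p.label == "framework")
    assert np.ptp(fw.energy) < 0.05


def test_empty_group_errors(toy):
    s, _ = toy
    with pytest.raises(ValueError, match="no receptor atoms"):
        subgroup_contributions(s, groups={"nothing": ("other",)},
                               angle_step=120.0)
    # MHC is a ligand-side tag: no receptor atoms carry it
    with pytest.raises(ValueError):
        subgroup_contributions(s, groups={"lig": ("MHC",)}, angle_step=120.0)


# ---------------------------------------------------------------------------
# Angular shift
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expect", [
    (350.0, 10.0, 20.0),
    (123.4, 123.4, 0.0),
    (0.0, 180.0, 180.0),
    (-30.0, 30.0, 60.0),
])
def test_angular_shift_examples(a, b, expect):
    assert angular_shift(a, b) == pytest.approx(expect)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(a=st.floats(-720, 720), b=st.floats(-720, 720))
def test_angular_shift_symmetric_and_bounded(a, b):
    d = angular_shift(a, b)
    assert 0.0 <= d <= 180.0
    assert d == pytest.approx(angular_shift(b, a))
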