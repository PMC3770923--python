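"""Rigid-body orientation scan: translate the receptor (TCR) away from the
ligand (pMHC) along its principal axis, rotate it through a full revolution,
and map the effective energy over the (distance x angle) grid.

The scan's premise is that the *polar* part of the effective energy (Coulomb
+ GB solvation) carries the orientation signal at long range, so the native
binding angle shows up as the landscape minimum without any induced fit.
Angle 0 is the pose as given in the input structure; for a bound input pose
the native orientation therefore sits at 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .constants import SCAN_CLASH_FRACTION
from .energetics import (DielectricModel, coulomb_pairs, gb_pair_matrix,
                         hct_effective_radii, lj_pairs)
from .structmodel import ParameterizedStructure, StructureError

angular_shift = geometry.angular_shift  # re-exported: minimal circular diff

DEFAULT_GROUPS = {
    "CDR1,2/MHC": ("CDR1a", "CDR2a", "CDR1b", "CDR2b"),
    "CDR3/peptide": ("CDR3a", "CDR3b"),
    "framework": ("framework",),
}


@dataclass
class OrientationLandscape:
    distances: np.ndarray      # A offsets along the axis
    angles: np.ndarray         # degrees in [0, 360)
    energy: np.ndarray         # (n_dist, n_angle) kcal/mol
    flagged: np.ndarray        # bool, steric-overlap grid points
    energy_mode: str

    @property
    def minimum(self):
        d, a, _e, _m = find_minimum(self)
        return d, a


@dataclass
class SubgroupProfile:
    label: str
    distance: float
    angles: np.ndarray
    energy: np.ndarray         # inter-partner polar energy vs angle
    share: float               # variance fraction of the orientation signal


def tcr_axis(structure: ParameterizedStructure):
    """Receptor principal axis and anchor point.

    Returns ``(axis, anchor)``: the principal gyration-tensor axis of the
    receptor's scored atoms most aligned with the receptor-to-ligand
    center-of-mass direction, sign-oriented toward the ligand; anchor is the
    receptor centroid (uniform atom weights). Raises on a degenerate
    (near-spherical) atom cloud, where no principal direction is defined.
    """
    if structure.partner_of is None:
        raise StructureError("partners not split")
    xyz = structure.coords
    rec = xyz[structure.receptor_mask]
    lig = xyz[structure.ligand_mask]
    if len(rec) < 3 or len(lig) == 0:
        raise StructureError("need receptor and ligand atoms")
    com_r = rec.mean(axis=0)
    com_l = lig.mean(axis=0)
    centred = rec - com_r
    gyr = centred.T @ centred / len(rec)
    evals, evecs = np.linalg.eigh(gyr)
    if (evals.max() - evals.min()) < 1e-6 * max(evals.max(), 1e-12):
        raise StructureError(
            "degenerate inertia tensor (near-spherical receptor); "
            "supply an explicit axis")
    direction = geometry.unit(com_l - com_r)
    align = np.abs(evecs.T @ direction)
    axis = evecs[:, int(np.argmax(align))]
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis, com_r


def _pose_coords(xyz, rec_mask, axis, dist, angle):
    """Receptor translated ``dist`` away from the ligand along ``axis``
    (which points receptor -> ligand) and rotated by ``angle`` degrees about
    the axis through its translated centroid; ligand untouched."""
    out = xyz.copy()
    shifted = xyz[rec_mask] - dist * axis
    centre = shifted.mean(axis=0)
    rot = geometry.rotation_about_axis(axis, angle)
    out[rec_mask] = (shifted - centre) @ rot.T + centre
    return out


def rigid_scan(structure: ParameterizedStructure,
               d_min: float = 6.0, d_max: float = 12.0, d_step: float = 2.0,
               angle_step: float = 5.0,
               energy_mode: str = "polar",
               axis=None,
               dielectric: DielectricModel | None = None,
               gb_scale: float = 0.8) -> OrientationLandscape:
    """Map the effective energy over rigid displacement and rotation of the
    receptor (ligand fixed; first frame only).

    Defaults follow the protocol this scan models: 6-12 A displacement and a
    5-degree angular grid covering [0, 360) exactly once (no duplicate
    360-degree endpoint). ``energy_mode``: "polar" sums Coulomb + GB only;
    "full" adds the inter-partner Lennard-Jones term. Grid points where any
    inter-partner heavy-atom pair comes closer than half the sum of vdW
    radii are flagged and excluded from the minimum search.
    """
    if not structure.parameterized or structure.partner_of is None:
        raise StructureError("need a parameterized, partner-split structure")
    if energy_mode not in ("polar", "full"):
        raise ValueError("energy_mode must be 'polar' or 'full'")
    dielectric = dielectric or DielectricModel()
    if axis is None:
        axis, _anchor = tcr_axis(structure)
    else:
        axis = geometry.unit(np.asarray(axis, dtype=float))

    distances = np.arange(d_min, d_max + 1e-9, d_step)
    angles = np.arange(0.0, 360.0, angle_step)
    scored = structure.receptor_mask | structure.ligand_mask
    rec_s = structure.receptor_mask[scored]
    heavy = np.array([e != "H" for e in structure.elements])[scored]
    q = structure.charges[scored]
    rho = structure.born[scored]
    rmin2 = structure.rmin2[scored]
    epsv = structure.eps[scored]
    xyz0 = structure.coords
    rec_mask_full = structure.receptor_mask

    hr = heavy & rec_s
    hl = heavy & ~rec_s
    clash_thresh = SCAN_CLASH_FRACTION * (rmin2[hr][:, None] + rmin2[hl][None, :])

    energy = np.empty((len(distances), len(angles)))
    flagged = np.zeros_like(energy, dtype=bool)
    for di, dist in enumerate(distances):
        for ai, ang in enumerate(angles):
            xyz = _pose_coords(xyz0, rec_mask_full, axis, dist, ang)
            sub = xyz[scored]
            d = np.linalg.norm(sub[hr][:, None, :] - sub[hl][None, :, :],
                               axis=-1)
            if np.any(d < clash_thresh):
                flagged[di, ai] = True
            elec = coulomb_pairs(sub[rec_s], q[rec_s], sub[~rec_s], q[~rec_s],
                                 dielectric.eps_in)
            a_eff = hct_effective_radii(sub, rho, scale=gb_scale)
            gb = float(gb_pair_matrix(sub, q, a_eff, dielectric).sum())
            total = elec + gb
            if energy_mode == "full":
                total += lj_pairs(sub[rec_s], rmin2[rec_s], epsv[rec_s],
                                  sub[~rec_s], rmin2[~rec_s], epsv[~rec_s])
            energy[di, ai] = total

    if np.all(flagged):
        raise StructureError(
            "empty valid grid: every pose is sterically overlapping")
    return OrientationLandscape(distances, angles, energy, flagged,
                                energy_mode)


def find_minimum(landscape: OrientationLandscape):
    """Global minimum over unflagged grid points.

    Returns ``(distance, angle, energy, margin)``; ties resolve to the
    smallest angle, then the smallest distance. ``margin`` is the energy gap
    from the global minimum to the lowest local minimum in a distinct basin
    (0 when the landscape is flat or no other basin exists).
    """
    e = np.where(landscape.flagged, np.inf, landscape.energy)
    if not np.isfinite(e).any():
        raise ValueError("all grid points are flagged")
    nd, na = e.shape
    best = None
    for ai in range(na):
        for di in range(nd):
            v = e[di, ai]
            if np.isfinite(v) and (best is None or v < best[0] - 1e-15):
                best = (v, di, ai)
    v0, di0, ai0 = best

    margin = None
    for di in range(nd):
        for ai in range(na):
            v = e[di, ai]
            if not np.isfinite(v):
                continue
            nb = [e[di, (ai - 1) % na], e[di, (ai + 1) % na]]
            if di > 0:
                nb.append(e[di - 1, ai])
            if di < nd - 1:
                nb.append(e[di + 1, ai])
            if not all(v <= x for x in nb):
                continue
            if (di, ai) == (di0, ai0):
                continue
            if abs(di - di0) <= 1 and min(abs(ai - ai0),
                                          na - abs(ai - ai0)) <= 1:
                continue  # same basin as the global minimum
            gap = v - v0
            margin = gap if margin is None else min(margin, gap)
    return (float(landscape.distances[di0]), float(landscape.angles[ai0]),
            float(v0), float(margin) if margin is not None else 0.0)


def subgroup_contributions(structure: ParameterizedStructure,
                           distance: float = 8.0,
                           angle_step: float = 5.0,
                           groups: dict | None = None,
                           axis=None,
                           dielectric: DielectricModel | None = None,
                           gb_scale: float = 0.8):
    """Decompose the inter-partner polar energy profile over receptor
    sub-groups (keyed by region tags) during rotation at a fixed
    displacement.

    A group's profile is the Coulomb + GB cross energy between its receptor
    residues and the whole ligand, so groups covering every receptor residue
    sum to the total inter-partner polar profile at each angle. ``share`` is
    var(group profile) / var(total profile) - the fraction of the
    orientation signal the group carries. Returns ``(profiles, total)``
    where ``total`` is a SubgroupProfile for the whole receptor.
    """
    if not structure.parameterized or structure.partner_of is None:
        raise StructureError("need a parameterized, partner-split structure")
    dielectric = dielectric or DielectricModel()
    groups = groups or DEFAULT_GROUPS
    if axis is None:
        axis, _ = tcr_axis(structure)
    else:
        axis = geometry.unit(np.asarray(axis, dtype=float))

    scored = structure.receptor_mask | structure.ligand_mask
    rec_s = structure.receptor_mask[scored]
    q = structure.charges[scored]
    rho = structure.born[scored]
    res_of = structure.res_index[scored]
    regions = np.array([structure.residues[ri].region for ri in res_of])

    group_masks = {}
    for label, tags in groups.items():
        m = rec_s & np.isin(regions, list(tags))
        if not m.any():
            raise ValueError(f"group {label!r} selects no receptor atoms")
        group_masks[label] = m

    angles = np.arange(0.0, 360.0, angle_step)
    lig = ~rec_s
    prof = {label: np.empty(len(angles)) for label in group_masks}
    total = np.empty(len(angles))
    for ai, ang in enumerate(angles):
        xyz = _pose_coords(structure.coords, structure.receptor_mask, axis,
                           distance, ang)
        sub = xyz[scored]
        a_eff = hct_effective_radii(sub, rho, scale=gb_scale)
        m = gb_pair_matrix(sub, q, a_eff, dielectric)
        for label, gmask in group_masks.items():
            elec = coulomb_pairs(sub[gmask], q[gmask], sub[lig], q[lig],
                                 dielectric.eps_in)
            gb_cross = 2.0 * m[np.ix_(gmask, lig)].sum()
            prof[label][ai] = elec + gb_cross
        total[ai] = (coulomb_pairs(sub[rec_s], q[rec_s], sub[lig], q[lig],
                                   dielectric.eps_in)
                     + 2.0 * m[np.ix_(rec_s, lig)].sum())

    var_total = float(np.var(total))
    out = []
    for label in group_masks:
        share = (float(np.var(prof[label])) / var_total
                 if var_total > 0 else 0.0)
        out.append(SubgroupProfile(label, distance, angles, prof[label], share))
    total_profile = SubgroupProfile("total", distance, angles, total, 1.0)
    return out, total_profile
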