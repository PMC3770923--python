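"""Implicit-solvent (MM-GBSA) effective and binding energies.

The binding free energy (entropy excluded) is assembled from four terms:

* ``elec`` - inter-partner Coulomb energy (gas phase),
* ``vdw``  - inter-partner Lennard-Jones energy,
* ``gb``   - Generalized Born electrostatic solvation,
* ``np``   - nonpolar solvation, proportional to the solvent accessible
  surface area (gamma * SASA + b; the additive constant enters absolute
  single-state values only and cancels in binding differences).

The single-trajectory convention is used throughout: receptor-alone and
ligand-alone terms are evaluated on the same frames after deleting the other
partner's atoms, so the conformational reorganisation term is zero by
construction and the inter-partner pair sums equal the binding deltas of the
gas-phase terms exactly.

Effective Born radii come from a Hawkins-Cramer-Truhlar style pairwise
descreening approximation; SASA from a deterministic Shrake-Rupley quadrature
on a golden-spiral point set. Every term is the arithmetic mean over frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import (B_DEFAULT, COULOMB_KCAL, EPS_IN_DEFAULT,
                        EPS_OUT_DEFAULT, GAMMA_DEFAULT, PROBE_RADIUS_DEFAULT)
from .structmodel import ParameterizedStructure, StructureError


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class DielectricModel:
    eps_in: float = EPS_IN_DEFAULT
    eps_out: float = EPS_OUT_DEFAULT

    def __post_init__(self):
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")

    @property
    def tau(self) -> float:
        return 1.0 / self.eps_in - 1.0 / self.eps_out


@dataclass(frozen=True)
class NonpolarParams:
    gamma: float = GAMMA_DEFAULT      # kcal/mol/A^2
    b: float = B_DEFAULT              # kcal/mol
    probe_radius: float = PROBE_RADIUS_DEFAULT

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")


@dataclass(frozen=True)
class EnergyBreakdown:
    """MM-GBSA terms in kcal/mol.

    ``intra`` is the conformational reorganisation term, fixed at zero in
    single-trajectory mode; ``entropy`` is a hook for an externally supplied
    -T*dS value (never computed here). ``total`` is the exact sum of all
    terms.
    """
    elec: float
    vdw: float
    gb: float
    np: float
    intra: float = 0.0
    entropy: float = 0.0

    @property
    def total(self) -> float:
        return self.elec + self.vdw + self.gb + self.np + self.intra + self.entropy

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.elec - other.elec, self.vdw - other.vdw,
                               self.gb - other.gb, self.np - other.np,
                               self.intra - other.intra,
                               self.entropy - other.entropy)

    def as_dict(self) -> dict:
        return {"elec": self.elec, "vdw": self.vdw, "gb": self.gb,
                "np": self.np, "intra": self.intra, "entropy": self.entropy,
                "total": self.total}


# ---------------------------------------------------------------------------
# Array-level primitives (single frame)
# ---------------------------------------------------------------------------

def coulomb_pairs(xyz_a, q_a, xyz_b, q_b, eps_in=EPS_IN_DEFAULT) -> float:
    """Sum of k_C * q_i q_j / (eps_in * r_ij) over all cross pairs."""
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0.0
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise EnergyError("overlapping atoms (r < 1e-6 A) between groups")
    return float(COULOMB_KCAL / eps_in * np.sum(np.outer(q_a, q_b) / d))


def lj_pairs(xyz_a, rmin2_a, eps_a, xyz_b, rmin2_b, eps_b) -> float:
    """Lennard-Jones cross-pair sum with Lorentz-Berthelot style combination:
    rmin_ij = rmin2_i + rmin2_j, eps_ij = sqrt(eps_i * eps_j)."""
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0.0
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise EnergyError("overlapping atoms (r < 1e-6 A) between groups")
    rmin = rmin2_a[:, None] + rmin2_b[None, :]
    epsij = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (rmin / d) ** 6
    return float(np.sum(epsij * (sr6 * sr6 - 2.0 * sr6)))


def hct_effective_radii(xyz, rho, scale: float = 0.8) -> np.ndarray:
    """Effective Born radii by pairwise descreening.

    ``rho`` are the intrinsic (input) Born radii; each neighbour j descreens
    atom i with a scaled radius ``scale * rho_j``. An isolated atom's
    effective radius equals its intrinsic radius exactly.
    """
    n = len(rho)
    if n == 0:
        return np.empty(0)
    inv = 1.0 / rho
    if n == 1:
        return rho.copy()
    r = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    sj = scale * rho[None, :]
    rho_i = rho[:, None]
    U = r + sj
    L = np.maximum(np.abs(r - sj), rho_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = ((1.0 / L - 1.0 / U)
                + 0.25 * (r - sj * sj / r) * (1.0 / (U * U) - 1.0 / (L * L))
                + 0.5 * np.log(L / U) / r)
    # no self-descreening; no contribution when j lies entirely inside rho_i
    np.fill_diagonal(term, 0.0)
    term[U <= rho_i] = 0.0
    term[r < 1e-6] = 0.0
    inv_eff = inv - 0.5 * np.nansum(term, axis=1)
    inv_eff = np.maximum(inv_eff, 1e-3)  # cap effective radii at 1000 A
    return 1.0 / inv_eff


def gb_pair_matrix(xyz, q, a_eff, dielectric: DielectricModel) -> np.ndarray:
    """Ordered pair matrix M with M[i,j] = -1/2 k_C tau q_i q_j / f_GB; the
    GB energy is ``M.sum()`` (diagonal = Born self terms)."""
    n = len(q)
    r2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    aa = np.outer(a_eff, a_eff)
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    return -0.5 * COULOMB_KCAL * dielectric.tau * np.outer(q, q) / f


def gb_total(xyz, q, rho, dielectric: DielectricModel,
             scale: float = 0.8) -> float:
    a_eff = hct_effective_radii(xyz, rho, scale=scale)
    return float(gb_pair_matrix(xyz, q, a_eff, dielectric).sum())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere point set."""
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


_SPHERE_CACHE: dict = {}


def _canonical_frame(xyz) -> np.ndarray:
    """Deterministic molecule-fixed orthonormal frame (principal axes of the
    coordinate cloud, signs fixed by the largest component). Rotating the
    molecule rotates this frame with it, which makes the numerical SASA
    quadrature exactly covariant under rigid transforms."""
    if len(xyz) < 2:
        return np.eye(3)
    c = xyz - xyz.mean(axis=0)
    gyr = c.T @ c
    _evals, evecs = np.linalg.eigh(gyr)
    basis = []
    for k in range(3):
        v = evecs[:, k]
        # sign from the third moment along the axis (rotates with the
        # molecule); fall back to the largest component for symmetric clouds
        proj = c @ v
        s3 = float(np.sum(proj ** 3))
        if abs(s3) > 1e-8 * (1.0 + float(np.sum(proj ** 2)) ** 1.5):
            if s3 < 0:
                v = -v
        else:
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
        basis.append(v)
    m = np.column_stack(basis)
    if np.linalg.det(m) < 0:
        m[:, 2] = -m[:, 2]
    return m


def sasa_per_atom(xyz, vdw_radii, probe_radius: float = PROBE_RADIUS_DEFAULT,
                  n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA per atom (A^2), deterministic point set aligned to
    the molecule's principal axes (rigid-transform covariant)."""
    if n_points not in _SPHERE_CACHE:
        _SPHERE_CACHE[n_points] = _sphere_points(n_points)
    pts = _SPHERE_CACHE[n_points] @ _canonical_frame(xyz).T
    radii = np.asarray(vdw_radii, dtype=float) + probe_radius
    n = len(radii)
    out = np.zeros(n)
    if n == 0:
        return out
    tree = cKDTree(xyz)
    rmax = radii.max()
    neighbours = [[] for _ in range(n)]
    for i, j in tree.query_pairs(2.0 * rmax):
        d = np.linalg.norm(xyz[i] - xyz[j])
        if d < radii[i] + radii[j]:
            neighbours[i].append(j)
            neighbours[j].append(i)
    for i in range(n):
        nbrs = neighbours[i]
        if not nbrs:
            out[i] = 4.0 * np.pi * radii[i] ** 2
            continue
        sphere = xyz[i] + radii[i] * pts
        d2 = np.sum((sphere[None, :, :] - xyz[nbrs][:, None, :]) ** 2, axis=-1)
        exposed = np.all(d2 > (radii[nbrs] ** 2)[:, None], axis=0)
        out[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return out


# ---------------------------------------------------------------------------
# Structure-level operations (frame-averaged)
# ---------------------------------------------------------------------------

def _group_atom_mask(structure: ParameterizedStructure, group) -> np.ndarray:
    """Group spec: 'receptor' / 'ligand', a boolean atom mask, or an iterable
    of residue indices."""
    if isinstance(group, str):
        if group == "receptor":
            return structure.receptor_mask
        if group == "ligand":
            return structure.ligand_mask
        raise ValueError(f"unknown group {group!r}")
    group = np.asarray(group)
    if group.dtype == bool:
        if group.shape != (structure.n_atoms,):
            raise ValueError("boolean group mask must have one entry per atom")
        return group
    return np.isin(structure.res_index, group)


def _require_params(structure):
    if not structure.parameterized:
        raise StructureError("structure is not parameterized")


def pair_elec(structure: ParameterizedStructure, group_a, group_b,
              eps_in: float = EPS_IN_DEFAULT) -> float:
    """Frame-averaged inter-group Coulomb energy (kcal/mol)."""
    _require_params(structure)
    ma = _group_atom_mask(structure, group_a)
    mb = _group_atom_mask(structure, group_b)
    if np.any(ma & mb):
        raise ValueError("groups must be disjoint")
    vals = [coulomb_pairs(fr[ma], structure.charges[ma],
                          fr[mb], structure.charges[mb], eps_in)
            for fr in structure.frames]
    return float(np.mean(vals))


def pair_vdw(structure: ParameterizedStructure, group_a, group_b) -> float:
    """Frame-averaged inter-group Lennard-Jones energy (kcal/mol)."""
    _require_params(structure)
    ma = _group_atom_mask(structure, group_a)
    mb = _group_atom_mask(structure, group_b)
    if np.any(ma & mb):
        raise ValueError("groups must be disjoint")
    vals = [lj_pairs(fr[ma], structure.rmin2[ma], structure.eps[ma],
                     fr[mb], structure.rmin2[mb], structure.eps[mb])
            for fr in structure.frames]
    return float(np.mean(vals))


def gb_energy(structure: ParameterizedStructure, subset=None,
              dielectric: DielectricModel | None = None,
              scale: float = 0.8) -> float:
    """Frame-averaged GB solvation energy of ``subset`` treated as an
    isolated solute (kcal/mol). ``subset=None`` means all atoms."""
    _require_params(structure)
    if structure.born is None or np.any(~np.isfinite(structure.born)):
        raise EnergyError("Born radii missing")
    dielectric = dielectric or DielectricModel()
    mask = (np.ones(structure.n_atoms, dtype=bool) if subset is None
            else _group_atom_mask(structure, subset))
    vals = [gb_total(fr[mask], structure.charges[mask], structure.born[mask],
                     dielectric, scale=scale)
            for fr in structure.frames]
    return float(np.mean(vals))


def sasa(structure: ParameterizedStructure, subset=None,
         probe_radius: float = PROBE_RADIUS_DEFAULT,
         n_points: int = 960):
    """Frame-averaged SASA of ``subset`` as an isolated molecule.

    Returns ``(total, per_atom)`` in A^2; per-atom areas sum to the total.
    """
    _require_params(structure)
    mask = (np.ones(structure.n_atoms, dtype=bool) if subset is None
            else _group_atom_mask(structure, subset))
    per = np.mean([sasa_per_atom(fr[mask], structure.rmin2[mask],
                                 probe_radius, n_points)
                   for fr in structure.frames], axis=0)
    return float(per.sum()), per


def effective_energy(structure: ParameterizedStructure,
                     dielectric: DielectricModel | None = None,
                     nonpolar: NonpolarParams | None = None,
                     mode: str = "full") -> EnergyBreakdown:
    """Inter-partner interaction energy plus whole-system solvation.

    ``mode='polar'`` keeps only the Coulomb and GB terms (the long-range
    electrostatic signal used for the orientation scan).
    """
    _require_params(structure)
    if structure.partner_of is None:
        raise StructureError("partners not split")
    dielectric = dielectric or DielectricModel()
    nonpolar = nonpolar or NonpolarParams()
    elec = pair_elec(structure, "receptor", "ligand", eps_in=dielectric.eps_in)
    gb = gb_energy(structure, None, dielectric)
    if mode == "polar":
        return EnergyBreakdown(elec, 0.0, gb, 0.0)
    vdw = pair_vdw(structure, "receptor", "ligand")
    total_sasa, _ = sasa(structure, None, nonpolar.probe_radius)
    np_term = nonpolar.gamma * total_sasa + nonpolar.b
    return EnergyBreakdown(elec, vdw, gb, np_term)


def binding_energy(structure: ParameterizedStructure,
                   dielectric: DielectricModel | None = None,
                   nonpolar: NonpolarParams | None = None,
                   sasa_points: int = 960,
                   entropy_term: float = 0.0) -> EnergyBreakdown:
    """Single-trajectory MM-GBSA binding energy (kcal/mol, entropy excluded
    unless an externally computed ``entropy_term`` (-T*dS) is supplied).

    Each term is X(complex) - X(receptor) - X(ligand) over the same frames;
    the gas-phase deltas reduce exactly to the inter-partner pair sums and
    the conformational term is zero by construction.
    """
    _require_params(structure)
    if structure.partner_of is None:
        raise StructureError("partners not split")
    dielectric = dielectric or DielectricModel()
    nonpolar = nonpolar or NonpolarParams()

    d_elec = pair_elec(structure, "receptor", "ligand", eps_in=dielectric.eps_in)
    d_vdw = pair_vdw(structure, "receptor", "ligand")

    scored = structure.receptor_mask | structure.ligand_mask
    gb_c = gb_energy(structure, scored, dielectric)
    gb_r = gb_energy(structure, "receptor", dielectric)
    gb_l = gb_energy(structure, "ligand", dielectric)

    s_c, _ = sasa(structure, scored, nonpolar.probe_radius, sasa_points)
    s_r, _ = sasa(structure, "receptor", nonpolar.probe_radius, sasa_points)
    s_l, _ = sasa(structure, "ligand", nonpolar.probe_radius, sasa_points)

    return EnergyBreakdown(d_elec, d_vdw, gb_c - gb_r - gb_l,
                           nonpolar.gamma * (s_c - s_r - s_l),
                           intra=0.0, entropy=entropy_term)
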