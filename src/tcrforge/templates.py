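"""Residue templates: per-atom partial charges, Lennard-Jones and Born radii,
ideal side-chain internal coordinates, rotamer sets, and H-bond donor/acceptor
roles for the 20 standard amino acids.

The parameter set is a self-consistent united-atom style table authored for
this toolkit: heavy atoms plus explicit *polar* hydrogens (backbone amide H,
hydroxyl/thiol/amine/amide/guanidinium H); nonpolar hydrogens are folded into
their heavy atoms. Per-template charges sum to the formal charge (ASP/GLU -1,
LYS/ARG +1, HIS neutral in the N-epsilon tautomer, all others 0). Any table in
the same TSV format can be swapped in at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

# ---------------------------------------------------------------------------
# Atom classes: (rmin/2 [A], epsilon [kcal/mol], intrinsic Born radius [A])
# ---------------------------------------------------------------------------
ATOM_CLASSES = {
    "C_ali": (2.00, 0.10, 1.95),   # united aliphatic carbon (CHn)
    "C_pol": (1.95, 0.07, 1.875),  # carbonyl / aromatic / guanidinium carbon
    "N": (1.85, 0.17, 1.625),
    "O": (1.70, 0.12, 1.48),
    "S": (2.00, 0.45, 1.775),
    "H_pol": (0.45, 0.046, 1.15),
}


@dataclass(frozen=True)
class AtomParams:
    element: str
    charge: float
    rmin2: float
    eps: float
    born: float


@dataclass(frozen=True)
class ZEntry:
    """One internal-coordinate construction line.

    ``tors`` is a fixed dihedral in degrees, or ("chi", k, offset) meaning the
    k-th free side-chain torsion plus a fixed branch offset.
    """
    name: str
    refs: tuple  # (a, b, c): dihedral a-b-c-name, angle b-c-name, bond c-name
    bond: float
    angle: float
    tors: object


@dataclass
class ResidueTemplate:
    name: str
    formal_charge: int
    atoms: dict  # name -> AtomParams, in canonical order
    zmatrix: list = field(default_factory=list)  # side-chain beyond CB + polar H
    n_chi: int = 0
    donors: list = field(default_factory=list)    # (heavy, hydrogen) pairs
    acceptors: list = field(default_factory=list)

    @property
    def heavy_atoms(self):
        return [n for n, p in self.atoms.items() if p.element != "H"]

    @property
    def polar_hydrogens(self):
        return [n for n, p in self.atoms.items() if p.element == "H"]


def _elem(name: str) -> str:
    if name.startswith("H"):
        return "H"
    for e in ("CL",):  # no halogens in standard residues; guard anyway
        if name.startswith(e):
            return e.capitalize()
    return name[0]


def _mk_atoms(entries):
    """entries: list of (name, class, charge)."""
    out = {}
    for name, cls, q in entries:
        rmin2, eps, born = ATOM_CLASSES[cls]
        out[name] = AtomParams(_elem(name), q, rmin2, eps, born)
    return out


# Backbone shared by all residues except PRO (which has no amide H).
_BB = [("N", "N", -0.35), ("H", "H_pol", 0.25), ("CA", "C_ali", 0.10),
       ("C", "C_pol", 0.50), ("O", "O", -0.50)]
_BB_PRO = [("N", "N", -0.20), ("CA", "C_ali", 0.10),
           ("C", "C_pol", 0.50), ("O", "O", -0.50)]

# CB is built from the backbone with a fixed branch geometry.
_CB = ZEntry("CB", ("C", "N", "CA"), 1.53, 110.5, -122.5)


def _z(name, refs, bond, angle, tors):
    return ZEntry(name, refs, bond, angle, tors)


def _chi(k, offset=0.0):
    return ("chi", k, offset)


_T = {}


def _add(name, formal, side_atoms, zmatrix, n_chi, donors=(), acceptors=(),
         pro=False):
    bb = _BB_PRO if pro else _BB
    atoms = _mk_atoms(bb + side_atoms)
    don = [("N", "H")] if not pro else []
    don += list(donors)
    acc = ["O"] + list(acceptors)
    zm = ([] if name == "GLY" else [_CB]) + zmatrix
    _T[name] = ResidueTemplate(name, formal, atoms, zm, n_chi, don, acc)


_add("GLY", 0, [], [], 0)
_add("ALA", 0, [("CB", "C_ali", 0.0)], [], 0)
_add("VAL", 0, [("CB", "C_ali", 0.0), ("CG1", "C_ali", 0.0), ("CG2", "C_ali", 0.0)],
     [_z("CG1", ("N", "CA", "CB"), 1.52, 110.5, _chi(1)),
      _z("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, 120.0))], 1)
_add("LEU", 0, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.0),
                ("CD1", "C_ali", 0.0), ("CD2", "C_ali", 0.0)],
     [_z("CG", ("N", "CA", "CB"), 1.53, 116.0, _chi(1)),
      _z("CD1", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2)),
      _z("CD2", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2, 120.0))], 2)
_add("ILE", 0, [("CB", "C_ali", 0.0), ("CG1", "C_ali", 0.0),
                ("CG2", "C_ali", 0.0), ("CD1", "C_ali", 0.0)],
     [_z("CG1", ("N", "CA", "CB"), 1.53, 110.5, _chi(1)),
      _z("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, -120.0)),
      _z("CD1", ("CA", "CB", "CG1"), 1.52, 113.0, _chi(2))], 2)
_add("PRO", 0, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.0), ("CD", "C_ali", 0.10)],
     [_z("CG", ("N", "CA", "CB"), 1.49, 104.0, -30.0),
      _z("CD", ("CA", "CB", "CG"), 1.50, 105.0, 30.0)], 0, pro=True)
_add("MET", 0, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.06),
                ("SD", "S", -0.12), ("CE", "C_ali", 0.06)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 114.0, _chi(1)),
      _z("SD", ("CA", "CB", "CG"), 1.80, 112.0, _chi(2)),
      _z("CE", ("CB", "CG", "SD"), 1.79, 100.0, _chi(3))], 3,
     acceptors=[])
_add("PHE", 0, [("CB", "C_ali", 0.0), ("CG", "C_pol", 0.0),
                ("CD1", "C_pol", 0.0), ("CD2", "C_pol", 0.0),
                ("CE1", "C_pol", 0.0), ("CE2", "C_pol", 0.0), ("CZ", "C_pol", 0.0)],
     [_z("CG", ("N", "CA", "CB"), 1.50, 114.0, _chi(1)),
      _z("CD1", ("CA", "CB", "CG"), 1.39, 120.0, _chi(2)),
      _z("CD2", ("CA", "CB", "CG"), 1.39, 120.0, _chi(2, 180.0)),
      _z("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
      _z("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
      _z("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)], 2)
_add("TYR", 0, [("CB", "C_ali", 0.0), ("CG", "C_pol", 0.0),
                ("CD1", "C_pol", 0.0), ("CD2", "C_pol", 0.0),
                ("CE1", "C_pol", 0.0), ("CE2", "C_pol", 0.0),
                ("CZ", "C_pol", 0.25), ("OH", "O", -0.65), ("HH", "H_pol", 0.40)],
     [_z("CG", ("N", "CA", "CB"), 1.50, 114.0, _chi(1)),
      _z("CD1", ("CA", "CB", "CG"), 1.39, 120.0, _chi(2)),
      _z("CD2", ("CA", "CB", "CG"), 1.39, 120.0, _chi(2, 180.0)),
      _z("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
      _z("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
      _z("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
      _z("OH", ("CD1", "CE1", "CZ"), 1.36, 120.0, 180.0),
      _z("HH", ("CE1", "CZ", "OH"), 0.96, 110.0, 180.0)], 2,
     donors=[("OH", "HH")], acceptors=["OH"])
_add("TRP", 0, [("CB", "C_ali", 0.0), ("CG", "C_pol", 0.0),
                ("CD1", "C_pol", 0.0), ("CD2", "C_pol", 0.0),
                ("NE1", "N", -0.55), ("HE1", "H_pol", 0.30),
                ("CE2", "C_pol", 0.25), ("CE3", "C_pol", 0.0),
                ("CZ2", "C_pol", 0.0), ("CZ3", "C_pol", 0.0), ("CH2", "C_pol", 0.0)],
     [_z("CG", ("N", "CA", "CB"), 1.50, 114.0, _chi(1)),
      _z("CD1", ("CA", "CB", "CG"), 1.37, 127.0, _chi(2)),
      _z("CD2", ("CA", "CB", "CG"), 1.43, 127.0, _chi(2, 180.0)),
      _z("NE1", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
      _z("CE2", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
      _z("CE3", ("CB", "CG", "CD2"), 1.40, 133.0, 0.0),
      _z("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.0, 180.0),
      _z("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.0, 180.0),
      _z("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.0, 180.0),
      _z("HE1", ("CG", "CD1", "NE1"), 1.01, 125.0, 180.0)], 2,
     donors=[("NE1", "HE1")])
_add("SER", 0, [("CB", "C_ali", 0.25), ("OG", "O", -0.65), ("HG", "H_pol", 0.40)],
     [_z("OG", ("N", "CA", "CB"), 1.42, 110.5, _chi(1)),
      _z("HG", ("CA", "CB", "OG"), 0.96, 109.5, 180.0)], 1,
     donors=[("OG", "HG")], acceptors=["OG"])
_add("THR", 0, [("CB", "C_ali", 0.25), ("OG1", "O", -0.65),
                ("HG1", "H_pol", 0.40), ("CG2", "C_ali", 0.0)],
     [_z("OG1", ("N", "CA", "CB"), 1.43, 109.5, _chi(1)),
      _z("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, -120.0)),
      _z("HG1", ("CA", "CB", "OG1"), 0.96, 109.5, 180.0)], 1,
     donors=[("OG1", "HG1")], acceptors=["OG1"])
_add("CYS", 0, [("CB", "C_ali", 0.10), ("SG", "S", -0.30), ("HG", "H_pol", 0.20)],
     [_z("SG", ("N", "CA", "CB"), 1.81, 113.0, _chi(1)),
      _z("HG", ("CA", "CB", "SG"), 1.34, 96.0, 180.0)], 1,
     donors=[("SG", "HG")])
_add("ASN", 0, [("CB", "C_ali", 0.0), ("CG", "C_pol", 0.55), ("OD1", "O", -0.55),
                ("ND2", "N", -0.60), ("HD21", "H_pol", 0.30), ("HD22", "H_pol", 0.30)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
      _z("OD1", ("CA", "CB", "CG"), 1.23, 121.0, _chi(2)),
      _z("ND2", ("CA", "CB", "CG"), 1.33, 116.0, _chi(2, 180.0)),
      _z("HD21", ("CB", "CG", "ND2"), 1.01, 120.0, 0.0),
      _z("HD22", ("CB", "CG", "ND2"), 1.01, 120.0, 180.0)], 2,
     donors=[("ND2", "HD21"), ("ND2", "HD22")], acceptors=["OD1"])
_add("GLN", 0, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.0), ("CD", "C_pol", 0.55),
                ("OE1", "O", -0.55), ("NE2", "N", -0.60),
                ("HE21", "H_pol", 0.30), ("HE22", "H_pol", 0.30)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 114.0, _chi(1)),
      _z("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
      _z("OE1", ("CB", "CG", "CD"), 1.23, 121.0, _chi(3)),
      _z("NE2", ("CB", "CG", "CD"), 1.33, 116.0, _chi(3, 180.0)),
      _z("HE21", ("CG", "CD", "NE2"), 1.01, 120.0, 0.0),
      _z("HE22", ("CG", "CD", "NE2"), 1.01, 120.0, 180.0)], 3,
     donors=[("NE2", "HE21"), ("NE2", "HE22")], acceptors=["OE1"])
_add("ASP", -1, [("CB", "C_ali", -0.10), ("CG", "C_pol", 0.50),
                 ("OD1", "O", -0.70), ("OD2", "O", -0.70)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
      _z("OD1", ("CA", "CB", "CG"), 1.25, 118.0, _chi(2)),
      _z("OD2", ("CA", "CB", "CG"), 1.25, 118.0, _chi(2, 180.0))], 2,
     acceptors=["OD1", "OD2"])
_add("GLU", -1, [("CB", "C_ali", 0.0), ("CG", "C_ali", -0.10), ("CD", "C_pol", 0.50),
                 ("OE1", "O", -0.70), ("OE2", "O", -0.70)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 114.0, _chi(1)),
      _z("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
      _z("OE1", ("CB", "CG", "CD"), 1.25, 118.0, _chi(3)),
      _z("OE2", ("CB", "CG", "CD"), 1.25, 118.0, _chi(3, 180.0))], 3,
     acceptors=["OE1", "OE2"])
_add("LYS", 1, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.0), ("CD", "C_ali", 0.0),
                ("CE", "C_ali", 0.25), ("NZ", "N", -0.30),
                ("HZ1", "H_pol", 0.35), ("HZ2", "H_pol", 0.35), ("HZ3", "H_pol", 0.35)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 114.0, _chi(1)),
      _z("CD", ("CA", "CB", "CG"), 1.52, 111.0, _chi(2)),
      _z("CE", ("CB", "CG", "CD"), 1.52, 111.0, _chi(3)),
      _z("NZ", ("CG", "CD", "CE"), 1.49, 112.0, _chi(4)),
      _z("HZ1", ("CD", "CE", "NZ"), 1.01, 109.5, 180.0),
      _z("HZ2", ("CD", "CE", "NZ"), 1.01, 109.5, 60.0),
      _z("HZ3", ("CD", "CE", "NZ"), 1.01, 109.5, -60.0)], 4,
     donors=[("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")])
_add("ARG", 1, [("CB", "C_ali", 0.0), ("CG", "C_ali", 0.0), ("CD", "C_ali", 0.20),
                ("NE", "N", -0.40), ("HE", "H_pol", 0.30), ("CZ", "C_pol", 0.70),
                ("NH1", "N", -0.60), ("HH11", "H_pol", 0.35), ("HH12", "H_pol", 0.35),
                ("NH2", "N", -0.60), ("HH21", "H_pol", 0.35), ("HH22", "H_pol", 0.35)],
     [_z("CG", ("N", "CA", "CB"), 1.52, 114.0, _chi(1)),
      _z("CD", ("CA", "CB", "CG"), 1.52, 111.0, _chi(2)),
      _z("NE", ("CB", "CG", "CD"), 1.46, 112.0, _chi(3)),
      _z("CZ", ("CG", "CD", "NE"), 1.33, 124.0, _chi(4)),
      _z("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
      _z("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
      _z("HE", ("NH1", "CZ", "NE"), 1.01, 120.0, 180.0),
      _z("HH11", ("NE", "CZ", "NH1"), 1.01, 120.0, 0.0),
      _z("HH12", ("NE", "CZ", "NH1"), 1.01, 120.0, 180.0),
      _z("HH21", ("NE", "CZ", "NH2"), 1.01, 120.0, 0.0),
      _z("HH22", ("NE", "CZ", "NH2"), 1.01, 120.0, 180.0)], 4,
     donors=[("NE", "HE"), ("NH1", "HH11"), ("NH1", "HH12"),
             ("NH2", "HH21"), ("NH2", "HH22")])
_add("HIS", 0, [("CB", "C_ali", 0.0), ("CG", "C_pol", 0.10), ("ND1", "N", -0.40),
                ("CD2", "C_pol", 0.10), ("CE1", "C_pol", 0.30),
                ("NE2", "N", -0.55), ("HE2", "H_pol", 0.45)],
     [_z("CG", ("N", "CA", "CB"), 1.50, 114.0, _chi(1)),
      _z("ND1", ("CA", "CB", "CG"), 1.38, 122.0, _chi(2)),
      _z("CD2", ("CA", "CB", "CG"), 1.36, 131.0, _chi(2, 180.0)),
      _z("CE1", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
      _z("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0),
      _z("HE2", ("CG", "CD2", "NE2"), 1.01, 125.0, 180.0)], 2,
     donors=[("NE2", "HE2")], acceptors=["ND1"])

TEMPLATES = _T

STANDARD_RESIDUES = tuple(sorted(TEMPLATES))

# Canonical rotamer chi values for free torsions
_ROTAMER_CHI = (-60.0, 180.0, 60.0)


def rotamer_chi_sets(resname: str):
    """Deterministic rotamer library: combinations of the canonical gauche-/
    trans/gauche+ values over the first two free torsions, remaining torsions
    trans. At most 9 rotamers per residue type."""
    t = TEMPLATES[resname]
    if t.n_chi == 0:
        return [()]
    n_free = min(2, t.n_chi)
    sets = []
    for combo in product(_ROTAMER_CHI, repeat=n_free):
        sets.append(tuple(combo) + (180.0,) * (t.n_chi - n_free))
    return sets


class ParameterTable:
    """Mapping (residue template, atom name) -> nonbonded parameters.

    The default table is the built-in template set above; alternative tables
    can be loaded from TSV (columns: template, atom, element, charge, rmin2,
    eps, born_radius).
    """

    def __init__(self, params: dict, formal_charges: dict, source: str = "custom"):
        self.params = params            # (resname, atom) -> AtomParams
        self.formal_charges = formal_charges
        self.source = source
        self._check_sums()

    def _check_sums(self):
        sums = {}
        for (res, _atom), p in self.params.items():
            sums[res] = sums.get(res, 0.0) + p.charge
        for res, s in sums.items():
            fc = self.formal_charges.get(res, 0)
            if abs(s - fc) > 1e-4:
                raise ValueError(
                    f"template {res}: charges sum to {s:.5f}, "
                    f"declared formal charge {fc}")

    @classmethod
    def default(cls) -> "ParameterTable":
        params = {}
        formal = {}
        for res, t in TEMPLATES.items():
            formal[res] = t.formal_charge
            for atom, p in t.atoms.items():
                params[(res, atom)] = p
        return cls(params, formal, source="tcrforge-builtin")

    def get(self, resname: str, atom: str):
        return self.params.get((resname, atom))

    def residue_atoms(self, resname: str):
        return [a for (r, a) in self.params if r == resname]

    def to_tsv(self, path):
        rows = []
        for (res, atom), p in sorted(self.params.items()):
            rows.append((res, atom, p.element, p.charge, p.rmin2, p.eps, p.born))
        df = pd.DataFrame(rows, columns=["template", "atom", "element",
                                         "charge", "rmin2", "eps", "born_radius"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, formal_charges=None) -> "ParameterTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        params = {}
        for row in df.itertuples(index=False):
            params[(row.template, row.atom)] = AtomParams(
                row.element, float(row.charge), float(row.rmin2),
                float(row.eps), float(row.born_radius))
        if formal_charges is None:
            sums = {}
            for (res, _a), p in params.items():
                sums[res] = sums.get(res, 0.0) + p.charge
            formal_charges = {r: int(round(s)) for r, s in sums.items()}
        return cls(params, formal_charges, source=str(path))
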