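"""Reading, parameterizing, annotating, and mutating protein complex
structures.

A :class:`ParameterizedStructure` holds one topology (atom names, per-atom
nonbonded parameters, residue identities) and one or more coordinate frames
over it; frames stand in for snapshots extracted from a simulation of the
complex. All downstream energetics consume this container.

Conventions: coordinates in Angstrom; residue identity is the author-assigned
(chain, sequence number, insertion code) and is never renumbered; altloc
conflicts resolve to the highest occupancy (tie -> 'A'); polar hydrogens are
constructed by ideal geometry at parameterization time when absent; nonpolar
hydrogens present in the input are dropped with a warning (the parameter set
is united-atom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser, PDBIO, StructureBuilder

from . import geometry
from .constants import CLASH_FRACTION
from .templates import TEMPLATES, ParameterTable, rotamer_chi_sets

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")

REGION_LABELS = ("CDR1a", "CDR2a", "CDR3a", "CDR1b", "CDR2b", "CDR3b",
                 "framework", "peptide", "MHC", "other")


class StructureError(ValueError):
    pass


class ParameterizationError(ValueError):
    pass


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray
    charge: float = np.nan
    lj_rmin: float = np.nan
    lj_eps: float = np.nan
    born_radius: float = np.nan


@dataclass(frozen=True)
class ResidueInfo:
    chain: str
    seq: int
    icode: str
    name: str
    region: str = "other"

    @property
    def rid(self):
        return (self.chain, self.seq, self.icode)

    @property
    def label(self):
        ic = self.icode.strip()
        return f"{self.chain}:{self.name}{self.seq}{ic}"


def parse_residue_id(rid) -> tuple:
    """Accept (chain, seq[, icode]) tuples or strings like 'D:12' / 'D:12A'."""
    if isinstance(rid, tuple):
        if len(rid) == 2:
            return (rid[0], int(rid[1]), " ")
        return (rid[0], int(rid[1]), rid[2] or " ")
    chain, _, rest = str(rid).partition(":")
    num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
    icode = rest[len(num):] or " "
    return (chain, int(num), icode)


@dataclass
class ParameterizedStructure:
    """Atoms with parameters, residue metadata, and >=1 coordinate frames."""

    atom_names: list
    elements: list
    res_index: np.ndarray            # (n_atoms,) int, into `residues`
    frames: np.ndarray               # (n_frames, n_atoms, 3) float
    residues: list                   # list[ResidueInfo]
    charges: np.ndarray | None = None
    rmin2: np.ndarray | None = None
    eps: np.ndarray | None = None
    born: np.ndarray | None = None
    partner_of: np.ndarray | None = None   # per-residue: 1=receptor, 2=ligand, 0=unscored
    parameter_source: str = ""
    skipped_residues: list = field(default_factory=list)

    # -- basic views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def parameterized(self) -> bool:
        return self.charges is not None

    @property
    def coords(self) -> np.ndarray:
        """First frame, (n_atoms, 3)."""
        return self.frames[0]

    def copy(self) -> "ParameterizedStructure":
        new = replace(self)
        new.atom_names = list(self.atom_names)
        new.elements = list(self.elements)
        new.res_index = self.res_index.copy()
        new.frames = self.frames.copy()
        new.residues = list(self.residues)
        for attr in ("charges", "rmin2", "eps", "born", "partner_of"):
            v = getattr(self, attr)
            if v is not None:
                setattr(new, attr, v.copy())
        new.skipped_residues = list(self.skipped_residues)
        return new

    def residue_index_of(self, rid) -> int:
        key = parse_residue_id(rid)
        for i, r in enumerate(self.residues):
            if r.rid == key:
                return i
        raise StructureError(f"residue {rid!r} not found")

    def atom_indices_of_residue(self, ri: int) -> np.ndarray:
        return np.nonzero(self.res_index == ri)[0]

    def atom_index(self, ri: int, name: str) -> int:
        for i in self.atom_indices_of_residue(ri):
            if self.atom_names[i] == name:
                return int(i)
        raise StructureError(
            f"atom {name} not found in residue {self.residues[ri].label}")

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def partner_atom_mask(self, which: int) -> np.ndarray:
        if self.partner_of is None:
            raise StructureError("partners not split; call split_partners first")
        return self.partner_of[self.res_index] == which

    @property
    def receptor_mask(self) -> np.ndarray:
        return self.partner_atom_mask(1)

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.partner_atom_mask(2)

    def chains(self) -> list:
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def get_residue_atoms(self, ri: int) -> list:
        out = []
        for i in self.atom_indices_of_residue(ri):
            out.append(Atom(
                self.atom_names[i], self.elements[i], self.frames[0, i].copy(),
                float(self.charges[i]) if self.charges is not None else np.nan,
                float(self.rmin2[i]) if self.rmin2 is not None else np.nan,
                float(self.eps[i]) if self.eps is not None else np.nan,
                float(self.born[i]) if self.born is not None else np.nan))
        return out


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _pick_altloc(atom):
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    children.sort(key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
    return children[0]


def read_structure(path, frame_policy: str = "first") -> ParameterizedStructure:
    """Read a PDB file into an unparameterized structure.

    ``frame_policy``: "first" keeps MODEL 1 only; "all" keeps every model as a
    frame (all models must share an identical topology).
    """
    if frame_policy not in ("first", "all"):
        raise ValueError("frame_policy must be 'first' or 'all'")
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:
        raise StructureError(f"unreadable PDB file {path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise StructureError(f"no models in {path}")
    if frame_policy == "first":
        models = models[:1]

    topo = None  # list of (chain, seq, icode, resname, atomname, element)
    frames = []
    for model in models:
        keys, coords = [], []
        for chain in model:
            for res in chain:
                het, seq, icode = res.get_id()
                if het == "W":
                    continue
                for atom in res:
                    atom = _pick_altloc(atom)
                    keys.append((chain.id, seq, icode, res.get_resname().strip(),
                                 atom.get_name()))
                    coords.append(atom.get_coord())
        if not keys:
            raise StructureError(f"zero atoms in a model of {path}")
        if topo is None:
            topo = keys
        elif keys != topo:
            raise StructureError("inconsistent models: atom topology differs "
                                 "between MODEL records")
        frames.append(np.asarray(coords, dtype=float))

    residues, res_index, atom_names, elements = [], [], [], []
    rid_to_idx = {}
    for (chain, seq, icode, resname, aname) in topo:
        rid = (chain, seq, icode)
        if rid not in rid_to_idx:
            rid_to_idx[rid] = len(residues)
            residues.append(ResidueInfo(chain, seq, icode, resname))
        res_index.append(rid_to_idx[rid])
        atom_names.append(aname)
        elements.append("H" if aname.startswith("H") else aname[0])

    return ParameterizedStructure(
        atom_names=atom_names, elements=elements,
        res_index=np.asarray(res_index, dtype=int),
        frames=np.stack(frames), residues=residues)


def write_structure(structure: ParameterizedStructure, path) -> None:
    """Write all frames as a (multi-)MODEL PDB file."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    for fi in range(structure.n_frames):
        builder.init_model(fi)
        current_chain = None
        for ri, res in enumerate(structure.residues):
            if res.chain != current_chain:
                builder.init_chain(res.chain)
                builder.init_seg("    ")
                current_chain = res.chain
            builder.init_residue(res.name, " ", res.seq, res.icode)
            for ai in structure.atom_indices_of_residue(ri):
                name = structure.atom_names[ai]
                fullname = name if len(name) == 4 else f" {name:<3s}"
                builder.init_atom(name, structure.frames[fi, ai], 0.0, 1.0,
                                  " ", fullname,
                                  element=structure.elements[ai])
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def _build_backbone_h(structure, frames, ri, prev_c_idx):
    """Ideal amide hydrogen: on the bisector opposite CA and the preceding
    carbonyl carbon (or this residue's own C at a chain start)."""
    n_i = structure.atom_index(ri, "N")
    ca_i = structure.atom_index(ri, "CA")
    other = prev_c_idx if prev_c_idx is not None else structure.atom_index(ri, "C")
    out = np.empty((frames.shape[0], 3))
    for f in range(frames.shape[0]):
        n, ca, oth = frames[f, n_i], frames[f, ca_i], frames[f, other]
        d = -(geometry.unit(ca - n) + geometry.unit(oth - n))
        out[f] = n + 1.0 * geometry.unit(d)
    return out


def assign_parameters(structure: ParameterizedStructure,
                      table: ParameterTable | None = None,
                      unknown_policy: str = "error") -> ParameterizedStructure:
    """Attach charges, LJ and Born parameters; construct missing polar H.

    ``unknown_policy``: "error" raises on unknown residues/atoms;
    "skip-residue" excludes the offending residue with a warning.
    Atoms are re-emitted in the template's canonical order. Idempotent.
    """
    if unknown_policy not in ("error", "skip-residue"):
        raise ValueError("unknown_policy must be 'error' or 'skip-residue'")
    if table is None:
        table = ParameterTable.default()

    new_names, new_elems, new_residx = [], [], []
    new_charges, new_rmin2, new_eps, new_born = [], [], [], []
    # coordinates assembled per frame
    per_frame_coords = [[] for _ in range(structure.n_frames)]
    new_residues = []
    skipped = []

    # map: residue -> index of its C atom (for amide H of the next residue)
    prev_c_by_res = {}
    for ri in range(structure.n_residues):
        try:
            prev_c_by_res[ri] = structure.atom_index(ri, "C")
        except StructureError:
            prev_c_by_res[ri] = None

    for ri, res in enumerate(structure.residues):
        tmpl = TEMPLATES.get(res.name)
        have = {structure.atom_names[i]: i
                for i in structure.atom_indices_of_residue(ri)}
        if tmpl is None or table.get(res.name, "CA") is None:
            msg = f"unknown residue template {res.name} at {res.label}"
            if unknown_policy == "error":
                raise ParameterizationError(msg)
            warnings.warn(msg + " - skipped")
            skipped.append(res.label)
            continue

        # drop any hydrogens that the united-atom template does not carry
        extra_h = [a for a in have
                   if a.startswith("H") and a not in tmpl.atoms]
        if extra_h:
            warnings.warn(f"{res.label}: dropping {len(extra_h)} hydrogens "
                          "not present in the united-atom template")
        unknown_heavy = [a for a in have
                         if not a.startswith("H") and a not in tmpl.atoms]
        missing_heavy = [a for a in tmpl.heavy_atoms if a not in have]
        if unknown_heavy or missing_heavy:
            msg = (f"{res.label}: atom mismatch with template {res.name} "
                   f"(unknown {unknown_heavy}, missing {missing_heavy})")
            if unknown_policy == "error":
                raise ParameterizationError(msg)
            warnings.warn(msg + " - skipped")
            skipped.append(res.label)
            continue

        # previous residue in the same chain, if contiguous in the file
        prev_c_idx = None
        if ri > 0 and structure.residues[ri - 1].chain == res.chain:
            prev_c_idx = prev_c_by_res[ri - 1]

        built_h = {}
        for hname in tmpl.polar_hydrogens:
            if hname in have:
                continue
            if hname == "H":
                built_h[hname] = _build_backbone_h(
                    structure, structure.frames, ri, prev_c_idx)
            else:
                entry = next(e for e in tmpl.zmatrix if e.name == hname)
                pos = np.empty((structure.n_frames, 3))
                a_i = structure.atom_index(ri, entry.refs[0])
                b_i = structure.atom_index(ri, entry.refs[1])
                c_i = structure.atom_index(ri, entry.refs[2])
                tors = entry.tors if not isinstance(entry.tors, tuple) else 180.0
                for f in range(structure.n_frames):
                    pos[f] = geometry.place_atom(
                        structure.frames[f, a_i], structure.frames[f, b_i],
                        structure.frames[f, c_i], entry.bond, entry.angle, tors)
                built_h[hname] = pos

        new_ri = len(new_residues)
        new_residues.append(res)
        for aname in tmpl.atoms:
            p = table.get(res.name, aname)
            if p is None:
                msg = f"{res.label}: atom {aname} missing from parameter table"
                if unknown_policy == "error":
                    raise ParameterizationError(msg)
                warnings.warn(msg + " - skipped")
                skipped.append(res.label)
                break
            if aname in have:
                src = structure.frames[:, have[aname], :]
            elif aname in built_h:
                src = built_h[aname]
            else:  # pragma: no cover - guarded by missing_heavy above
                raise ParameterizationError(f"{res.label}: cannot place {aname}")
            new_names.append(aname)
            new_elems.append(p.element)
            new_residx.append(new_ri)
            new_charges.append(p.charge)
            new_rmin2.append(p.rmin2)
            new_eps.append(p.eps)
            new_born.append(p.born)
            for f in range(structure.n_frames):
                per_frame_coords[f].append(src[f])

    if not new_names:
        raise ParameterizationError("no residues could be parameterized")

    frames = np.stack([np.asarray(c) for c in per_frame_coords])
    out = ParameterizedStructure(
        atom_names=new_names, elements=new_elems,
        res_index=np.asarray(new_residx, dtype=int), frames=frames,
        residues=new_residues,
        charges=np.asarray(new_charges), rmin2=np.asarray(new_rmin2),
        eps=np.asarray(new_eps), born=np.asarray(new_born),
        parameter_source=table.source, skipped_residues=skipped)
    if structure.partner_of is not None:
        # remap partner labels by residue identity
        old = {r.rid: structure.partner_of[i]
               for i, r in enumerate(structure.residues)}
        out.partner_of = np.array([old.get(r.rid, 0) for r in out.residues])
    return out


# ---------------------------------------------------------------------------
# Partner split and region tagging
# ---------------------------------------------------------------------------

def split_partners(structure: ParameterizedStructure,
                   receptor_chains, ligand_chains) -> ParameterizedStructure:
    """Record which chains form the receptor (TCR) and the ligand (pMHC)."""
    rset, lset = set(receptor_chains), set(ligand_chains)
    overlap = rset & lset
    if overlap:
        raise StructureError(f"receptor/ligand chain overlap: {sorted(overlap)}")
    present = set(structure.chains())
    missing = (rset | lset) - present
    if missing:
        raise StructureError(f"missing chain(s): {sorted(missing)}")
    out = structure.copy()
    out.partner_of = np.array(
        [1 if r.chain in rset else (2 if r.chain in lset else 0)
         for r in out.residues])
    return out


@dataclass
class RegionMap:
    """chain + inclusive residue ranges -> region label."""

    entries: list  # list of (chain, start, end, region)

    def __post_init__(self):
        by_chain = {}
        for chain, start, end, region in self.entries:
            if region not in REGION_LABELS:
                raise ValueError(f"unknown region label {region!r}")
            if end < start:
                raise ValueError(f"bad range {start}-{end}")
            for s, e in by_chain.get(chain, []):
                if start <= e and end >= s:
                    raise ValueError(
                        f"overlapping ranges on chain {chain}: "
                        f"{start}-{end} vs {s}-{e}")
            by_chain.setdefault(chain, []).append((start, end))

    @classmethod
    def from_dict(cls, d: dict) -> "RegionMap":
        """{"D": [[26, 31, "CDR1a"], ...], ...}"""
        entries = []
        for chain, ranges in d.items():
            for start, end, region in ranges:
                entries.append((chain, int(start), int(end), region))
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "RegionMap":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def lookup(self, chain: str, seq: int):
        for c, start, end, region in self.entries:
            if c == chain and start <= seq <= end:
                return region
        return None


def tag_regions(structure: ParameterizedStructure,
                region_map: RegionMap) -> ParameterizedStructure:
    """Assign region labels; untouched receptor residues default to
    'framework', untouched ligand residues to 'other'."""
    chains = set(structure.chains())
    for c, start, end, _region in region_map.entries:
        if c not in chains:
            raise StructureError(f"region map chain {c} not in structure")
        seqs = [r.seq for r in structure.residues if r.chain == c]
        if not any(start <= s <= end for s in seqs):
            raise StructureError(
                f"range {start}-{end} outside chain {c} "
                f"(residues {min(seqs)}-{max(seqs)})")
    out = structure.copy()
    new_res = []
    for i, r in enumerate(out.residues):
        region = region_map.lookup(r.chain, r.seq)
        if region is None:
            if out.partner_of is not None and out.partner_of[i] == 1:
                region = "framework"
            else:
                region = "other"
        new_res.append(replace(r, region=region))
    out.residues = new_res
    return out


# ---------------------------------------------------------------------------
# Mutant builders
# ---------------------------------------------------------------------------

def _strip_residue_atoms(structure, ri, keep_names):
    """Return atom index mask keeping all atoms except those of residue `ri`
    not named in keep_names."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    for ai in structure.atom_indices_of_residue(ri):
        if structure.atom_names[ai] not in keep_names:
            mask[ai] = False
    return mask


def _apply_atom_mask(structure, mask):
    out = structure.copy()
    out.atom_names = [n for n, m in zip(out.atom_names, mask) if m]
    out.elements = [e for e, m in zip(out.elements, mask) if m]
    out.res_index = out.res_index[mask]
    out.frames = out.frames[:, mask, :]
    for attr in ("charges", "rmin2", "eps", "born"):
        v = getattr(out, attr)
        if v is not None:
            setattr(out, attr, v[mask])
    return out


def build_alanine_mutant(structure: ParameterizedStructure,
                         residue_id,
                         table: ParameterTable | None = None
                         ) -> ParameterizedStructure:
    """Truncate a residue's side-chain to C-beta and retype it as alanine.

    Backbone and C-beta coordinates are untouched in every frame. An ALA
    target returns an identical copy; GLY (no C-beta) and PRO (ring spans the
    backbone) raise :class:`MutationError`.
    """
    if not structure.parameterized:
        raise MutationError("structure must be parameterized first")
    if table is None:
        table = ParameterTable.default()
    ri = structure.residue_index_of(residue_id)
    res = structure.residues[ri]
    if res.name == "ALA":
        return structure.copy()
    if res.name == "GLY":
        raise MutationError(f"{res.label}: GLY has no C-beta to truncate to")
    if res.name == "PRO":
        raise MutationError(f"{res.label}: PRO ring spans the backbone")
    if res.name not in TEMPLATES:
        raise MutationError(f"{res.label}: not a standard amino acid")

    keep = set(BACKBONE_ATOMS) | {"CB"}
    out = _apply_atom_mask(structure, _strip_residue_atoms(structure, ri, keep))
    out.residues = list(out.residues)
    out.residues[ri] = replace(res, name="ALA")
    for ai in out.atom_indices_of_residue(ri):
        p = table.get("ALA", out.atom_names[ai])
        out.charges[ai] = p.charge
        out.rmin2[ai] = p.rmin2
        out.eps[ai] = p.eps
        out.born[ai] = p.born
    return out


def build_point_mutant(structure: ParameterizedStructure, residue_id,
                       new_template: str,
                       table: ParameterTable | None = None
                       ) -> ParameterizedStructure:
    """Replace one residue by another standard amino acid.

    Backbone and the shared side-chain prefix keep wild-type coordinates; new
    atoms are placed by ideal internal geometry, choosing the canonical
    rotamer with the lowest steric overlap against the rest of the structure
    (hard-sphere threshold 0.6 x sum of vdW radii). Deterministic.
    """
    if not structure.parameterized:
        raise MutationError("structure must be parameterized first")
    if table is None:
        table = ParameterTable.default()
    new_template = new_template.upper()
    if new_template not in TEMPLATES:
        raise MutationError(f"{new_template} is not a standard amino acid")
    ri = structure.residue_index_of(residue_id)
    res = structure.residues[ri]
    if res.name not in TEMPLATES:
        raise MutationError(f"{res.label}: not a standard amino acid")
    if res.name == new_template:
        return structure.copy()
    if new_template == "GLY" or res.name == "GLY":
        # GLY has no CB; treat as pure truncation / growth from backbone
        pass

    tmpl_new = TEMPLATES[new_template]
    old_names = {structure.atom_names[i]
                 for i in structure.atom_indices_of_residue(ri)}

    # shared prefix: walk the new template's construction order and keep an
    # atom's wild-type coordinates only if it and all its references survive
    kept = set(n for n in BACKBONE_ATOMS if n in old_names and n in tmpl_new.atoms)
    build_entries = []
    for entry in tmpl_new.zmatrix:
        refs_ok = all(r in kept for r in entry.refs)
        if entry.name in old_names and refs_ok and not entry.name.startswith("H"):
            kept.add(entry.name)
        else:
            build_entries.append(entry)
    # CB handled by zmatrix entry when present in template order
    if "CB" in tmpl_new.atoms and "CB" in old_names:
        kept.add("CB")
        build_entries = [e for e in build_entries if e.name != "CB"]

    base = _apply_atom_mask(structure, _strip_residue_atoms(structure, ri, kept))
    base.residues = list(base.residues)
    base.residues[ri] = replace(res, name=new_template)

    def build_coords(chis, frame_idx, coords_by_name):
        """Place build_entries for one frame; returns dict name->xyz."""
        placed = dict(coords_by_name)
        for entry in build_entries:
            if isinstance(entry.tors, tuple):
                _tag, k, offset = entry.tors
                tors = chis[k - 1] + offset
            else:
                tors = entry.tors
            a, b, c = (placed[r] for r in entry.refs)
            placed[entry.name] = geometry.place_atom(
                a, b, c, entry.bond, entry.angle, tors)
        return {e.name: placed[e.name] for e in build_entries}

    def frame_anchor_coords(frame_idx):
        d = {}
        for ai in base.atom_indices_of_residue(ri):
            d[base.atom_names[ai]] = base.frames[frame_idx, ai]
        return d

    # rotamer selection on frame 0 against all other heavy atoms
    other_mask = np.ones(base.n_atoms, dtype=bool)
    other_mask[base.atom_indices_of_residue(ri)] = False
    other_mask &= base.heavy_mask()
    other_xyz = base.frames[0][other_mask]
    other_r = base.rmin2[other_mask]

    best = None
    anchors0 = frame_anchor_coords(0)
    for chis in rotamer_chi_sets(new_template):
        placed = build_coords(chis, 0, anchors0)
        score, clashes = 0.0, []
        for name, xyz in placed.items():
            if name.startswith("H"):
                continue
            p = table.get(new_template, name)
            if other_xyz.size:
                d = np.linalg.norm(other_xyz - xyz, axis=1)
                thresh = CLASH_FRACTION * (other_r + p.rmin2)
                bad = d < thresh
                score += float(np.sum(np.maximum(0.0, thresh - d)))
                for j in np.nonzero(bad)[0]:
                    clashes.append((name, float(d[j])))
        key = (len(clashes), score)
        if best is None or key < best[0]:
            best = (key, chis, clashes)
    (_nclash, _score), chis, clashes = best
    if _nclash > 0:
        detail = ", ".join(f"{n} at {d:.2f} A" for n, d in clashes[:5])
        raise MutationError(
            f"{res.label} -> {new_template}: all rotamers clash ({detail})")

    # rebuild the atom list in canonical order, with the mutated residue's
    # atoms (kept wild-type coordinates + newly placed ones) in template order
    names2, elems2, residx2 = [], [], []
    charges2, rmin22, eps2, born2 = [], [], [], []
    frames2 = [[] for _ in range(base.n_frames)]
    done_mut = False

    def emit_mut():
        anchors = {f: frame_anchor_coords(f) for f in range(base.n_frames)}
        built = {f: build_coords(chis, f, anchors[f]) for f in range(base.n_frames)}
        if "H" in tmpl_new.atoms and all("H" not in anchors[f] for f in anchors):
            # amide H absent (e.g. PRO source): ideal bisector construction
            prev_c = None
            if ri > 0 and base.residues[ri - 1].chain == res.chain:
                try:
                    prev_c = base.atom_index(ri - 1, "C")
                except StructureError:
                    prev_c = None
            for f in range(base.n_frames):
                n = anchors[f]["N"]
                ca = anchors[f]["CA"]
                oth = base.frames[f, prev_c] if prev_c is not None else anchors[f]["C"]
                d = -(geometry.unit(ca - n) + geometry.unit(oth - n))
                built[f]["H"] = n + geometry.unit(d)
        for aname in tmpl_new.atoms:
            p = table.get(new_template, aname)
            names2.append(aname)
            elems2.append(p.element)
            residx2.append(ri)
            charges2.append(p.charge)
            rmin22.append(p.rmin2)
            eps2.append(p.eps)
            born2.append(p.born)
            for f in range(base.n_frames):
                if aname in anchors[f]:
                    frames2[f].append(np.asarray(anchors[f][aname], dtype=float))
                else:
                    frames2[f].append(np.asarray(built[f][aname], dtype=float))

    for ai in range(base.n_atoms):
        rcur = int(base.res_index[ai])
        if rcur == ri:
            if not done_mut:
                emit_mut()
                done_mut = True
            continue
        names2.append(base.atom_names[ai])
        elems2.append(base.elements[ai])
        residx2.append(rcur)
        charges2.append(float(base.charges[ai]))
        rmin22.append(float(base.rmin2[ai]))
        eps2.append(float(base.eps[ai]))
        born2.append(float(base.born[ai]))
        for f in range(base.n_frames):
            frames2[f].append(base.frames[f, ai])
    if not done_mut:  # residue had no atoms left (should not happen)
        emit_mut()

    out = ParameterizedStructure(
        atom_names=names2, elements=elems2,
        res_index=np.asarray(residx2, dtype=int),
        frames=np.stack([np.asarray(c) for c in frames2]),
        residues=base.residues,
        charges=np.asarray(charges2), rmin2=np.asarray(rmin22),
        eps=np.asarray(eps2), born=np.asarray(born2),
        partner_of=base.partner_of,
        parameter_source=base.parameter_source,
        skipped_residues=base.skipped_residues)
    return out
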