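"""Hydrogen-bond and nonpolar-contact detection over conformational
ensembles, and occurrence maps binned by a separation coordinate xi.

An occurrence map answers: for a focus group (an atom or residue), which
partner atoms does it interact with, and in what fraction of frames, at each
protein-protein separation? The xi label of each frame comes from metadata
(a per-frame table), so any ensemble source works - the module does not
generate dissociation pathways itself.

H-bond criteria are geometric and config-exposed: donor-acceptor distance
<= 3.5 A and donor-H...acceptor angle >= 120 degrees by default; the
donor/acceptor roles come from the residue template table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HBOND_ANGLE_CUTOFF, HBOND_DA_CUTOFF, NP_CONTACT_CUTOFF
from .structmodel import ParameterizedStructure, StructureError
from .templates import TEMPLATES


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = HBOND_DA_CUTOFF       # donor-acceptor distance, A
    angle_cutoff: float = HBOND_ANGLE_CUTOFF  # donor-H...acceptor angle, deg


@dataclass(frozen=True)
class HBond:
    donor_res: tuple      # residue id (chain, seq, icode)
    donor_atom: str
    hydrogen: str
    acceptor_res: tuple
    acceptor_atom: str
    distance: float       # donor-acceptor, A
    angle: float          # donor-H...acceptor, deg

    @property
    def key(self):
        return (self.donor_res, self.donor_atom,
                self.acceptor_res, self.acceptor_atom)


@dataclass
class OccurrenceMap:
    focus: tuple                 # residue id (and optionally atom name)
    partners: list               # (residue id, atom name) ever observed
    bin_edges: np.ndarray
    fractions: np.ndarray        # (n_partners, n_bins) in [0, 1]
    n_frames: np.ndarray         # frames per retained bin


def _donor_triples(structure):
    """(heavy_index, h_index, residue_index) for every donor with its H."""
    out = []
    for ri, res in enumerate(structure.residues):
        tmpl = TEMPLATES.get(res.name)
        if tmpl is None:
            continue
        names = {structure.atom_names[i]: int(i)
                 for i in structure.atom_indices_of_residue(ri)}
        for heavy, hyd in tmpl.donors:
            if heavy in names and hyd in names:
                out.append((names[heavy], names[hyd], ri))
            elif heavy in names:
                raise StructureError(
                    f"{res.label}: donor {heavy} lacks hydrogen {hyd}; "
                    "re-parameterize the structure to build polar hydrogens")
    return out


def _acceptor_indices(structure):
    out = []
    for ri, res in enumerate(structure.residues):
        tmpl = TEMPLATES.get(res.name)
        if tmpl is None:
            continue
        names = {structure.atom_names[i]: int(i)
                 for i in structure.atom_indices_of_residue(ri)}
        for acc in tmpl.acceptors:
            if acc in names:
                out.append((names[acc], ri))
    return out


def detect_hbonds(structure: ParameterizedStructure, frame: int = 0,
                  criteria: HBondCriteria | None = None,
                  across_partners_only: bool = True):
    """Geometric H-bond detection in one frame.

    Donors/acceptors come from the residue templates; by default only bonds
    crossing the receptor/ligand split are reported.
    """
    criteria = criteria or HBondCriteria()
    xyz = structure.frames[frame]
    donors = _donor_triples(structure)
    acceptors = _acceptor_indices(structure)
    partner = structure.partner_of
    out = []
    for d_i, h_i, d_ri in donors:
        for a_i, a_ri in acceptors:
            if a_ri == d_ri:
                continue
            if across_partners_only:
                if partner is None:
                    raise StructureError("partners not split")
                pd, pa = partner[d_ri], partner[a_ri]
                if pd == 0 or pa == 0 or pd == pa:
                    continue
            dist = float(np.linalg.norm(xyz[d_i] - xyz[a_i]))
            if dist > criteria.da_cutoff:
                continue
            v1 = xyz[d_i] - xyz[h_i]
            v2 = xyz[a_i] - xyz[h_i]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < criteria.angle_cutoff:
                continue
            dres = structure.residues[d_ri]
            ares = structure.residues[a_ri]
            out.append(HBond(dres.rid, structure.atom_names[d_i],
                             structure.atom_names[h_i],
                             ares.rid, structure.atom_names[a_i],
                             dist, angle))
    return out


def detect_np_contacts(structure: ParameterizedStructure, frame: int = 0,
                       cutoff: float = NP_CONTACT_CUTOFF):
    """Nonpolar contacts: carbon/sulfur heavy-atom pairs across the
    receptor/ligand split within ``cutoff`` (A)."""
    if structure.partner_of is None:
        raise StructureError("partners not split")
    xyz = structure.frames[frame]
    nonpolar = np.isin(structure.elements, ("C", "S"))
    rec = structure.receptor_mask & nonpolar
    lig = structure.ligand_mask & nonpolar
    ri_idx = np.nonzero(rec)[0]
    li_idx = np.nonzero(lig)[0]
    if len(ri_idx) == 0 or len(li_idx) == 0:
        return []
    d = np.linalg.norm(xyz[ri_idx][:, None, :] - xyz[li_idx][None, :, :],
                       axis=-1)
    out = []
    for i, j in zip(*np.nonzero(d <= cutoff)):
        ai, aj = int(ri_idx[i]), int(li_idx[j])
        out.append(((structure.residues[structure.res_index[ai]].rid,
                     structure.atom_names[ai]),
                    (structure.residues[structure.res_index[aj]].rid,
                     structure.atom_names[aj]),
                    float(d[i, j])))
    return out


def occurrence_map(structure: ParameterizedStructure, xi_per_frame,
                   focus, bin_edges,
                   criteria: HBondCriteria | None = None,
                   kind: str = "hbond",
                   focus_atom: str | None = None) -> OccurrenceMap:
    """Fraction of frames, per xi bin, in which each partner interaction of
    the focus residue (optionally a single focus atom) exists.

    ``xi_per_frame``: one separation value per frame; frames falling in
    empty bins are impossible, but bins containing no frames are dropped
    with a warning. Partners never observed are not listed.
    """
    import warnings

    xi = np.asarray(xi_per_frame, dtype=float)
    if xi.shape[0] != structure.n_frames:
        raise ValueError("need one xi label per frame")
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges) - 1
    which = np.digitize(xi, bin_edges) - 1
    valid = (which >= 0) & (which < n_bins)

    focus_rid = structure.residues[structure.residue_index_of(focus)].rid

    # collect per-frame interaction keys involving the focus
    per_frame_keys = []
    for f in range(structure.n_frames):
        keys = set()
        if kind == "hbond":
            for hb in detect_hbonds(structure, f, criteria):
                if hb.donor_res == focus_rid:
                    if focus_atom and focus_atom not in (hb.donor_atom,
                                                         hb.hydrogen):
                        continue
                    keys.add((hb.acceptor_res, hb.acceptor_atom))
                elif hb.acceptor_res == focus_rid:
                    if focus_atom and hb.acceptor_atom != focus_atom:
                        continue
                    keys.add((hb.donor_res, hb.donor_atom))
        elif kind == "nonpolar":
            for (a, b, _d) in detect_np_contacts(structure, f):
                if a[0] == focus_rid and (not focus_atom or a[1] == focus_atom):
                    keys.add(b)
                elif b[0] == focus_rid and (not focus_atom or b[1] == focus_atom):
                    keys.add(a)
        else:
            raise ValueError("kind must be 'hbond' or 'nonpolar'")
        per_frame_keys.append(keys)

    counts_per_bin = np.zeros(n_bins, dtype=int)
    for f in range(structure.n_frames):
        if valid[f]:
            counts_per_bin[which[f]] += 1
    keep = counts_per_bin > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty xi bins")

    partners = sorted({k for keys in per_frame_keys for k in keys})
    frac = np.zeros((len(partners), n_bins))
    for f in range(structure.n_frames):
        if not valid[f]:
            continue
        b = which[f]
        for k in per_frame_keys[f]:
            frac[partners.index(k), b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts_per_bin > 0, frac / counts_per_bin, np.nan)
    return OccurrenceMap(focus_rid, partners, bin_edges,
                         frac[:, keep], counts_per_bin[keep])
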