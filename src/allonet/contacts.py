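"""Typed inter-residue contact detection and differential fingerprinting.

Five interaction types are detected per frame — hydrogen bonds, ionic
(salt-bridge) contacts, π-stacking, π-cation and hydrophobic contacts —
with geometric criteria matching common contact-analysis defaults, except
that the hydrogen bond additionally requires a D–H···A angle of at least
150°.  Per-system contact frequencies (fraction of frames a pair shows a
given interaction type) feed a differential comparison between two systems
in which a pair is flagged as *differentiating* when its frequency changes
by more than a threshold (default 40 percentage points), plus a residue-role
classification (ligand-binding / interlobe-interface at a 50% persistence
rule) and a chord-diagram export.

Chemistry tables (donors, acceptors, charged atoms, aromatic rings, Bondi
van der Waals radii) cover the 20 standard amino acids and ATP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (AtomSelection, FrameEnsemble, HYDROPHOBIC_RESNAMES,
                    Topology)

__all__ = [
    "ContactCriteria",
    "ContactTable",
    "DifferentialTable",
    "detect_contacts",
    "contact_frequencies",
    "differential_contacts",
    "classify_residues",
    "export_chord",
]

# --------------------------------------------------------------------------
# Chemistry tables (standard amino acids + ATP)
# --------------------------------------------------------------------------

# Side-chain donor heavy atoms; the backbone amide N donates for every residue.
SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "HIS": ["ND1", "NE2"], "TRP": ["NE1"],
    "ATP": ["N6", "O2'", "O3'"],
}
BACKBONE_DONOR = "N"

# Acceptor heavy atoms; the backbone carbonyl O accepts for every residue.
SIDECHAIN_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"], "MET": ["SD"],
    "ASN": ["OD1"], "GLN": ["OE1"], "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
    "ATP": ["N1", "N3", "N7", "O4'", "O2'", "O3'", "O5'",
            "O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"],
}
BACKBONE_ACCEPTORS = ("O", "OXT", "OT1", "OT2")

ANIONIC_ATOMS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "ATP": ["O1A", "O2A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"],
}
CATIONIC_ATOMS = {
    "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2", "CZ"], "HIS": ["ND1", "NE2"],
}

AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
            ["CG", "CD1", "NE1", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "ATP": [["N1", "C2", "N3", "C4", "C5", "C6"],
            ["C4", "C5", "N7", "C8", "N9"]],
}

# Bondi van der Waals radii, nm.
VDW_RADII_NM = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "P": 0.180,
                "H": 0.120}

_HB_COVALENT_NM = 0.125     # H attached to a donor heavy atom within this distance


@dataclass
class ContactCriteria:
    """Geometric thresholds for the five interaction types (nm / degrees)."""

    hbond_distance_nm: float = 0.35       # donor-acceptor heavy-atom distance
    hbond_angle_deg: float = 150.0        # minimum D-H...A angle
    ionic_distance_nm: float = 0.40
    pi_stack_distance_nm: float = 0.70    # ring-centroid distance
    pi_stack_angle_deg: float = 30.0      # maximum angle between ring normals
    pi_cation_distance_nm: float = 0.60
    pi_cation_angle_deg: float = 60.0     # maximum normal-to-cation offset angle
    hydrophobic_margin_nm: float = 0.05   # added to the vdW radius sum

    def __post_init__(self) -> None:
        for name in ("hbond_distance_nm", "ionic_distance_nm", "pi_stack_distance_nm",
                     "pi_cation_distance_nm", "hydrophobic_margin_nm",
                     "hbond_angle_deg", "pi_stack_angle_deg", "pi_cation_angle_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONTACT_TYPES = ("hbond", "ionic", "pi_stack", "pi_cation", "hydrophobic")


@dataclass
class ContactTable:
    """Per-(residue i, residue j, type) contact frequencies for one system.

    Keys use internal residue indices with i < j; ``frequency`` is exactly
    contact-frame count / total frames.
    """

    data: pd.DataFrame          # columns: resindex_i, resindex_j, type, count, frequency
    n_frames: int
    topology: Optional[Topology] = field(default=None, repr=False)

    def frequency(self, i: int, j: int, ctype: str) -> float:
        i, j = min(i, j), max(i, j)
        rows = self.data[(self.data.resindex_i == i) & (self.data.resindex_j == j)
                         & (self.data.type == ctype)]
        return float(rows.frequency.iloc[0]) if len(rows) else 0.0

    def to_tsv(self, path: str) -> None:
        df = self.data.copy()
        if self.topology is not None:
            df["residue_i"] = [self.topology.residue_label(i) for i in df.resindex_i]
            df["residue_j"] = [self.topology.residue_label(j) for j in df.resindex_j]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DifferentialTable:
    """Union-keyed comparison of two contact tables; Δ in percentage points."""

    data: pd.DataFrame          # resindex_i/j, type, f_a, f_b, delta_pp, flagged
    threshold_pp: float
    topology: Optional[Topology] = field(default=None, repr=False)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.data[self.data.flagged]

    def to_tsv(self, path: str) -> None:
        df = self.data.copy()
        if self.topology is not None:
            df["residue_i"] = [self.topology.residue_label(i) for i in df.resindex_i]
            df["residue_j"] = [self.topology.residue_label(j) for j in df.resindex_j]
        df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Per-frame detection
# --------------------------------------------------------------------------

class _ResidueChem:
    """Cached per-residue chemistry lookups against one topology."""

    def __init__(self, topology: Topology):
        self.top = topology
        t = topology
        self.res_atoms = [np.flatnonzero(t.resindices == r)
                          for r in range(t.n_residues)]
        self.heavy = t.is_heavy
        names = t.atom_names
        self.donors, self.acceptors = [], []
        self.anionic, self.cationic = [], []
        self.rings = []
        self.hydrogens = []
        for r in range(t.n_residues):
            resname = str(t.resnames[r])
            idx = self.res_atoms[r]
            by_name = {}
            for i in idx:
                by_name.setdefault(names[i], i)
            don = [by_name[BACKBONE_DONOR]] if BACKBONE_DONOR in by_name else []
            don += [by_name[a] for a in SIDECHAIN_DONORS.get(resname, []) if a in by_name]
            acc = [by_name[a] for a in BACKBONE_ACCEPTORS if a in by_name]
            acc += [by_name[a] for a in SIDECHAIN_ACCEPTORS.get(resname, []) if a in by_name]
            self.donors.append(don)
            self.acceptors.append(acc)
            self.anionic.append([by_name[a] for a in ANIONIC_ATOMS.get(resname, [])
                                 if a in by_name])
            self.cationic.append([by_name[a] for a in CATIONIC_ATOMS.get(resname, [])
                                  if a in by_name])
            rings = []
            for ring in AROMATIC_RINGS.get(resname, []):
                members = [by_name[a] for a in ring if a in by_name]
                if len(members) == len(ring):
                    rings.append(np.array(members))
            self.rings.append(rings)
            self.hydrogens.append(np.array([i for i in idx if t.elements[i] == "H"],
                                           dtype=np.intp))
        self.has_hydrogens = any(len(h) for h in self.hydrogens)
        self.hydrophobic_res = np.array(
            [str(n) in HYDROPHOBIC_RESNAMES for n in t.resnames], dtype=bool)
        self.heavy_atoms = [idx[self.heavy[idx]] for idx in self.res_atoms]
        self.vdw = np.array([VDW_RADII_NM.get(str(e), 0.17) for e in t.elements])
        self.is_backbone = t.is_backbone


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond(chem: _ResidueChem, coords: np.ndarray, ri: int, rj: int,
           crit: ContactCriteria) -> bool:
    sequential = abs(ri - rj) <= 1
    for d_res, a_res in ((ri, rj), (rj, ri)):
        for d in chem.donors[d_res]:
            hyds = chem.hydrogens[d_res]
            if len(hyds) == 0:
                continue
            hd = np.linalg.norm(coords[hyds] - coords[d], axis=1)
            attached = hyds[hd <= _HB_COVALENT_NM]
            if len(attached) == 0:
                continue
            for a in chem.acceptors[a_res]:
                if sequential and chem.is_backbone[d] and chem.is_backbone[a]:
                    continue  # trivial neighbour backbone-backbone H-bond
                if np.linalg.norm(coords[d] - coords[a]) > crit.hbond_distance_nm:
                    continue
                for h in attached:
                    if _angle_deg(coords[d], coords[h], coords[a]) >= crit.hbond_angle_deg:
                        return True
    return False


def _min_cross_distance(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def _ring_geometry(coords: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = coords[members]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # ring normal = smallest principal axis of the member cloud
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def detect_contacts(coords: np.ndarray, topology: Topology,
                    criteria: Optional[ContactCriteria] = None,
                    chem: Optional[_ResidueChem] = None,
                    warn_no_hydrogens: bool = True) -> set[tuple[int, int, str]]:
    """All typed contacts in one frame as {(resindex_i, resindex_j, type)}, i < j.

    Intra-residue contacts are never reported; sequence-neighbour
    backbone-backbone hydrogen bonds are excluded.  Hydrogen-bond detection is
    disabled (with a warning) when the topology carries no hydrogens.
    """
    criteria = criteria or ContactCriteria()
    chem = chem or _ResidueChem(topology)
    if warn_no_hydrogens and not chem.has_hydrogens:
        import warnings
        warnings.warn("topology has no hydrogens: hydrogen-bond detection disabled",
                      stacklevel=2)
    n_res = topology.n_residues
    # candidate pairs: residues whose heavy atoms come within the coarsest cutoff
    reach = max(criteria.hbond_distance_nm, criteria.ionic_distance_nm,
                criteria.pi_stack_distance_nm, criteria.pi_cation_distance_nm,
                2 * max(VDW_RADII_NM.values()) + criteria.hydrophobic_margin_nm)
    centers = np.array([coords[chem.heavy_atoms[r]].mean(axis=0)
                        if len(chem.heavy_atoms[r]) else coords[chem.res_atoms[r]].mean(axis=0)
                        for r in range(n_res)])
    radii = np.array([
        np.max(np.linalg.norm(coords[chem.heavy_atoms[r]] - centers[r], axis=1))
        if len(chem.heavy_atoms[r]) else 0.0
        for r in range(n_res)])
    out: set[tuple[int, int, str]] = set()
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if np.linalg.norm(centers[i] - centers[j]) > reach + radii[i] + radii[j]:
                continue
            out |= _pair_contacts(chem, coords, i, j, criteria)
    return out


def _pair_contacts(chem: _ResidueChem, coords: np.ndarray, ri: int, rj: int,
                   crit: ContactCriteria) -> set[tuple[int, int, str]]:
    found = set()
    # hydrogen bond
    if chem.has_hydrogens and _hbond(chem, coords, ri, rj, crit):
        found.add((ri, rj, "hbond"))
    # ionic
    for an_res, cat_res in ((ri, rj), (rj, ri)):
        if chem.anionic[an_res] and chem.cationic[cat_res]:
            if _min_cross_distance(coords, np.array(chem.anionic[an_res]),
                                   np.array(chem.cationic[cat_res])) <= crit.ionic_distance_nm:
                found.add((ri, rj, "ionic"))
                break
    # pi-stacking
    if chem.rings[ri] and chem.rings[rj]:
        for ring_i in chem.rings[ri]:
            for ring_j in chem.rings[rj]:
                ci, ni = _ring_geometry(coords, ring_i)
                cj, nj = _ring_geometry(coords, ring_j)
                if np.linalg.norm(ci - cj) > crit.pi_stack_distance_nm:
                    continue
                cosang = abs(ni @ nj)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= crit.pi_stack_angle_deg:
                    found.add((ri, rj, "pi_stack"))
    # pi-cation
    for ring_res, cat_res in ((ri, rj), (rj, ri)):
        if chem.rings[ring_res] and chem.cationic[cat_res]:
            for ring in chem.rings[ring_res]:
                c, nvec = _ring_geometry(coords, ring)
                for cat in chem.cationic[cat_res]:
                    v = coords[cat] - c
                    dist = np.linalg.norm(v)
                    if dist > crit.pi_cation_distance_nm or dist < 1e-9:
                        continue
                    offset = np.degrees(np.arccos(np.clip(abs(nvec @ v) / dist, -1, 1)))
                    if offset <= crit.pi_cation_angle_deg:
                        found.add((ri, rj, "pi_cation"))
    # hydrophobic
    if chem.hydrophobic_res[ri] and chem.hydrophobic_res[rj]:
        ia, ib = chem.heavy_atoms[ri], chem.heavy_atoms[rj]
        if len(ia) and len(ib):
            diff = coords[ia][:, None, :] - coords[ib][None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
            limit = (chem.vdw[ia][:, None] + chem.vdw[ib][None, :]
                     + crit.hydrophobic_margin_nm)
            if np.any(dist <= limit):
                found.add((ri, rj, "hydrophobic"))
    return found


def contact_frequencies(ensemble: FrameEnsemble,
                        criteria: Optional[ContactCriteria] = None) -> ContactTable:
    """Exact per-(pair, type) contact frame fractions over the ensemble."""
    criteria = criteria or ContactCriteria()
    chem = _ResidueChem(ensemble.topology)
    counts: dict[tuple[int, int, str], int] = {}
    for f in range(ensemble.n_frames):
        for key in detect_contacts(ensemble.coords[f], ensemble.topology, criteria,
                                   chem=chem, warn_no_hydrogens=(f == 0)):
            counts[key] = counts.get(key, 0) + 1
    rows = [(i, j, t, c, c / ensemble.n_frames)
            for (i, j, t), c in sorted(counts.items())]
    df = pd.DataFrame(rows, columns=["resindex_i", "resindex_j", "type",
                                     "count", "frequency"])
    return ContactTable(df, ensemble.n_frames, ensemble.topology)


def differential_contacts(a: ContactTable, b: ContactTable,
                          threshold_pp: float = 40.0) -> DifferentialTable:
    """Union-keyed frequency difference Δ = f_B − f_A in percentage points.

    Pairs absent from one table count as frequency 0 there; |Δ| strictly
    greater than the threshold flags the pair as differentiating.
    """
    if (a.topology is not None and b.topology is not None
            and a.topology.n_residues != b.topology.n_residues):
        raise ValueError("contact tables use different residue numbering")
    fa = {(r.resindex_i, r.resindex_j, r.type): r.frequency
          for r in a.data.itertuples()}
    fb = {(r.resindex_i, r.resindex_j, r.type): r.frequency
          for r in b.data.itertuples()}
    rows = []
    for key in sorted(set(fa) | set(fb)):
        va = fa.get(key, 0.0)
        vb = fb.get(key, 0.0)
        delta = (vb - va) * 100.0
        rows.append((*key, va, vb, delta, abs(delta) > threshold_pp))
    df = pd.DataFrame(rows, columns=["resindex_i", "resindex_j", "type",
                                     "f_a", "f_b", "delta_pp", "flagged"])
    return DifferentialTable(df, threshold_pp, a.topology or b.topology)


def classify_residues(table: ContactTable, ligand_resindices: Sequence[int],
                      lobe_map: dict[int, str], threshold: float = 0.5
                      ) -> dict[int, str]:
    """Label residues as ligand-binding / interlobe-interface / both / neither.

    A residue binds the ligand if any contact type with any ligand residue
    persists for at least ``threshold`` of the frames (any-type rule,
    configurable via the criteria used to build the table); it sits at the
    interlobe interface if any contact with a residue of the opposite lobe
    does.  ``lobe_map`` maps residue index -> lobe label and must cover every
    protein residue in the table.
    """
    ligand = set(int(r) for r in ligand_resindices)
    roles: dict[int, set] = {}
    for row in table.data.itertuples():
        i, j, f = row.resindex_i, row.resindex_j, row.frequency
        if f < threshold:
            continue
        for this, other in ((i, j), (j, i)):
            if this in ligand:
                continue
            if other in ligand:
                roles.setdefault(this, set()).add("ligand")
            else:
                if this not in lobe_map or other not in lobe_map:
                    raise KeyError(f"residue {this if this not in lobe_map else other} "
                                   "missing from lobe map")
                if lobe_map[this] != lobe_map[other]:
                    roles.setdefault(this, set()).add("interlobe")
    out = {}
    residues = sorted(set(table.data.resindex_i) | set(table.data.resindex_j) - ligand)
    for r in residues:
        if r in ligand:
            continue
        tags = roles.get(r, set())
        if "ligand" in tags and "interlobe" in tags:
            out[r] = "both"
        elif "ligand" in tags:
            out[r] = "ATP-binding"
        elif "interlobe" in tags:
            out[r] = "interlobe-interface"
        else:
            out[r] = "neither"
    return out


def export_chord(diff: DifferentialTable, roles: Optional[dict[int, str]],
                 path: str, flagged_only: bool = False) -> None:
    """Write a flareplot-style JSON chord description plus a TSV twin."""
    top = diff.topology
    df = diff.flagged if flagged_only else diff.data

    def label(r):
        return top.residue_label(r) if top is not None else str(r)

    edges = [{
        "name1": label(row.resindex_i),
        "name2": label(row.resindex_j),
        "type": row.type,
        "f_a": float(row.f_a),
        "f_b": float(row.f_b),
        "delta_pp": float(row.delta_pp),
        "flagged": bool(row.flagged),
    } for row in df.itertuples()]
    nodes = {}
    if roles:
        nodes = {label(r): role for r, role in roles.items()}
    with open(path, "w") as fh:
        json.dump({"edges": edges, "nodes": nodes,
                   "threshold_pp": diff.threshold_pp}, fh, indent=1)
    tsv_path = path.rsplit(".", 1)[0] + ".tsv"
    df.to_csv(tsv_path, sep="\t", index=False)
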