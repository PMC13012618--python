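"""Core structural model: topologies, coordinate ensembles, selections, superposition.

Everything downstream (order parameters, contacts, dynamic networks, free
energy) operates on the two containers defined here:

* :class:`Topology` — static atom/residue bookkeeping (names, elements,
  source residue numbering, chains, backbone/heavy flags).
* :class:`FrameEnsemble` — an ``(F, A, 3)`` coordinate array in nanometres
  plus an optional per-frame time axis in picoseconds.

File I/O (PDB, GRO, XTC, DCD) is delegated to MDAnalysis; coordinates are
converted to nm on read and back to Å where a format requires it.  Residue
numbering is always the source file's numbering (1-based author numbering),
never re-indexed.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Topology",
    "FrameEnsemble",
    "AtomSelection",
    "SelectionError",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "superpose",
    "kabsch",
]

# Backbone heavy atoms incl. terminal variants; hydrogens are never backbone here.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2", "O1", "O2"})

# Purely hydrophobic residues (used by the hydrophobic-contact criterion).
HYDROPHOBIC_RESNAMES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "TRP"})

_TWO_LETTER_ELEMENTS = {"MG", "CL", "NA", "ZN", "FE", "MN", "BR", "SE", "CU", "NI", "CD"}

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "NA": 22.990, "CL": 35.45, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "BR": 79.904, "SE": 78.971, "CU": 63.546,
    "NI": 58.693, "CD": 112.414, "X": 0.0,
}


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB-style atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    upper = stripped.upper()
    # Two-letter symbols only for bare ion-style names (MG, CL...); side-chain
    # names such as CD1 (carbon delta) must fall through to the first letter.
    if len(upper) <= 2 and upper in _TWO_LETTER_ELEMENTS:
        return upper
    return upper[0]


class SelectionError(ValueError):
    """Raised for malformed selection expressions or unknown names."""


@dataclass
class Topology:
    """Static atom and residue bookkeeping shared by all frames of an ensemble.

    Atom order is stable and identical to the trajectory atom order.  Residues
    keep the source file's numbering (``resids``) alongside a contiguous
    0-based internal index (``resindices``).
    """

    atom_names: np.ndarray          # (A,) str
    elements: np.ndarray            # (A,) str
    resindices: np.ndarray          # (A,) int, 0-based internal residue index
    resids: np.ndarray              # (R,) int, source numbering
    resnames: np.ndarray            # (R,) str
    chains: np.ndarray              # (R,) str

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resindices = np.asarray(self.resindices, dtype=np.intp)
        self.resids = np.asarray(self.resids, dtype=np.intp)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        if self.n_atoms == 0:
            raise ValueError("topology must contain at least one atom")
        if self.resindices.min() < 0 or self.resindices.max() >= self.n_residues:
            raise ValueError("atom resindices out of range")
        for c in np.unique(self.chains):
            rid = self.resids[self.chains == c]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue indices within chain {c!r} must be non-decreasing")

    # -- derived per-atom properties -------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.resids)

    @property
    def atom_resids(self) -> np.ndarray:
        return self.resids[self.resindices]

    @property
    def atom_resnames(self) -> np.ndarray:
        return self.resnames[self.resindices]

    @property
    def atom_chains(self) -> np.ndarray:
        return self.chains[self.resindices]

    @property
    def is_backbone(self) -> np.ndarray:
        return np.array([n in BACKBONE_NAMES for n in self.atom_names], dtype=bool)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    @property
    def is_hydrophobic_residue(self) -> np.ndarray:
        return np.array([r in HYDROPHOBIC_RESNAMES for r in self.atom_resnames], dtype=bool)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 0.0) for e in self.elements], dtype=float)

    def atoms_of_residue(self, resindex: int) -> np.ndarray:
        return np.flatnonzero(self.resindices == resindex)

    def residue_label(self, resindex: int) -> str:
        return f"{self.chains[resindex]}:{self.resnames[resindex]}:{self.resids[resindex]}"

    @classmethod
    def from_atom_records(
        cls,
        atom_names: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        chains: Optional[Sequence[str]] = None,
        elements: Optional[Sequence[str]] = None,
    ) -> "Topology":
        """Build a topology from flat per-atom records.

        Residues are delimited by any change in ``(chain, resid, resname)``
        along the atom order, so duplicate author numbers in different chains
        survive intact.
        """
        n = len(atom_names)
        if chains is None:
            chains = ["A"] * n
        if elements is None:
            elements = [element_from_name(a) for a in atom_names]
        resindices = np.empty(n, dtype=np.intp)
        r_ids, r_names, r_chains = [], [], []
        prev_key = None
        for i in range(n):
            key = (chains[i], int(resids[i]), resnames[i])
            if key != prev_key:
                r_ids.append(int(resids[i]))
                r_names.append(resnames[i])
                r_chains.append(chains[i])
                prev_key = key
            resindices[i] = len(r_ids) - 1
        return cls(
            atom_names=np.asarray(atom_names, dtype=object),
            elements=np.asarray(elements, dtype=object),
            resindices=resindices,
            resids=np.asarray(r_ids),
            resnames=np.asarray(r_names, dtype=object),
            chains=np.asarray(r_chains, dtype=object),
        )


@dataclass
class FrameEnsemble:
    """F frames × A atoms × 3 coordinates, in nanometres."""

    topology: Topology
    coords: np.ndarray                       # (F, A, 3) nm
    times: Optional[np.ndarray] = None       # (F,) ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, A, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset_frames(self, idx) -> "FrameEnsemble":
        t = None if self.times is None else self.times[idx]
        return FrameEnsemble(self.topology, self.coords[idx], t)

    def concat(self, other: "FrameEnsemble") -> "FrameEnsemble":
        if other.topology.n_atoms != self.topology.n_atoms:
            raise ValueError("atom count mismatch in concat")
        times = None
        if self.times is not None and other.times is not None:
            times = np.concatenate([self.times, other.times])
        return FrameEnsemble(self.topology, np.concatenate([self.coords, other.coords]), times)


@dataclass
class AtomSelection:
    """Ordered, unique atom indices into a topology, with the source expression."""

    indices: np.ndarray
    expression: str = ""
    topology: Optional[Topology] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if self.topology is not None and len(self.indices):
            if self.indices.min() < 0 or self.indices.max() >= self.topology.n_atoms:
                raise ValueError("selection index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def require_nonempty(self) -> "AtomSelection":
        if len(self.indices) == 0:
            raise SelectionError(f"selection {self.expression!r} is empty")
        return self


# ---------------------------------------------------------------------------
# Selection mini-grammar
#
#   expr      := term ("or" term)*
#   term      := factor ("and" factor)*
#   factor    := "not" factor | "(" expr ")" | primitive
#   primitive := "resid" range+ | "resname" NAME+ | "name" NAME+
#              | "chain" NAME+ | "backbone" | "heavy" | "calpha" | "all"
#   range     := INT | INT "-" INT
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "resid", "resname", "name", "chain",
             "backbone", "heavy", "calpha", "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    out = []
    for raw in re.findall(r"\(|\)|[^\s()]+", expression):
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def _collect_args(self) -> list[str]:
        args = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            args.append(self.next())
        if not args:
            raise SelectionError("keyword requires at least one argument")
        return args

    def primitive(self) -> np.ndarray:
        tok = self.next()
        top = self.top
        if tok == "backbone":
            return top.is_backbone
        if tok == "heavy":
            return top.is_heavy
        if tok == "calpha":
            mask = np.array([n == "CA" for n in top.atom_names], dtype=bool)
            return mask
        if tok == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if tok == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            resids = top.atom_resids
            for arg in self._collect_args():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
                if not m:
                    raise SelectionError(f"bad resid range {arg!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise SelectionError(f"empty resid range {arg!r}")
                mask |= (resids >= lo) & (resids <= hi)
            return mask
        if tok in ("resname", "name", "chain"):
            source = {"resname": top.atom_resnames,
                      "name": top.atom_names,
                      "chain": top.atom_chains}[tok]
            known = set(source.tolist())
            mask = np.zeros(top.n_atoms, dtype=bool)
            for arg in self._collect_args():
                if arg not in known:
                    raise SelectionError(f"unknown {tok} {arg!r} in topology")
                mask |= np.array([s == arg for s in source], dtype=bool)
            return mask
        raise SelectionError(f"unexpected token {tok!r}")


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression, returning topology-ordered atom indices.

    Pure function of ``(topology, expression)``; unknown residue/atom/chain
    names raise :class:`SelectionError` rather than returning empty results.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return AtomSelection(np.flatnonzero(mask), expression, topology)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target.

    Returns ``(R, t)`` with ``mobile @ R.T + t ~= target``; proper rotation
    enforced via the determinant correction.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def _check_fit_atoms(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise ValueError("superposition requires at least 3 fit atoms")
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10:
        raise ValueError("fit atoms are collinear or coincident; superposition is degenerate")


def superpose(
    ensemble: FrameEnsemble,
    fit_selection: AtomSelection,
    reference: int = 0,
) -> tuple[FrameEnsemble, np.ndarray]:
    """Rigidly fit every frame onto the reference frame over the fit selection.

    Returns the transformed ensemble (all atoms moved) and the per-frame
    post-fit RMSD (nm) over the fit selection.
    """
    fit_selection.require_nonempty()
    idx = fit_selection.indices
    ref = ensemble.coords[reference][idx]
    _check_fit_atoms(ref)
    out = np.empty_like(ensemble.coords)
    rmsd = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        R, t = kabsch(ensemble.coords[f][idx], ref)
        out[f] = ensemble.coords[f] @ R.T + t
        diff = out[f][idx] - ref
        rmsd[f] = np.sqrt((diff ** 2).sum() / len(idx))
    times = None if ensemble.times is None else ensemble.times.copy()
    return FrameEnsemble(ensemble.topology, out, times), rmsd


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_NM_PER_ANGSTROM = 0.1


def _universe_to_topology(u) -> Topology:
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    try:
        elements = [str(e).upper() if str(e).strip() else element_from_name(n)
                    for e, n in zip(atoms.elements, names)]
    except Exception:
        elements = [element_from_name(n) for n in names]
    try:
        chains = [str(c) for c in atoms.chainIDs]
    except Exception:
        chains = [str(s) for s in atoms.segids]
    chains = [c if c.strip() else "A" for c in chains]
    return Topology.from_atom_records(
        atom_names=names,
        resids=[int(r) for r in atoms.resids],
        resnames=[str(r) for r in atoms.resnames],
        chains=chains,
        elements=elements,
    )


def load_structure(path: str, fmt: Optional[str] = None) -> tuple[Topology, FrameEnsemble]:
    """Read a PDB or GRO file into a topology plus one frame per model."""
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    kwargs = {"format": fmt} if fmt else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path, **kwargs)
    if len(u.atoms) == 0:
        raise ValueError(f"no atoms parsed from {path}")
    top = _universe_to_topology(u)
    frames, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float) * _NM_PER_ANGSTROM)
            times.append(float(ts.time) if ts.time is not None else float(ts.frame))
    return top, FrameEnsemble(top, np.array(frames), np.array(times))


def load_trajectory(topology: Topology, path: str, fmt: Optional[str] = None,
                    topology_path: Optional[str] = None) -> FrameEnsemble:
    """Read an XTC/DCD/multi-model-PDB trajectory against an existing topology.

    ``topology_path`` supplies the structure file MDAnalysis needs for
    coordinate-only formats; a minimal in-memory structure is synthesized from
    ``topology`` when omitted.
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    kwargs = {"format": fmt} if fmt else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology_path is not None:
            u = mda.Universe(topology_path, path, **kwargs)
        else:
            u = _empty_universe(topology)
            try:
                u.load_new(path, **kwargs)
            except ValueError as exc:
                raise ValueError(
                    f"trajectory atom count does not match topology "
                    f"atom count {topology.n_atoms}: {exc}"
                ) from exc
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {len(u.atoms)} does not match topology "
            f"atom count {topology.n_atoms}"
        )
    frames, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float) * _NM_PER_ANGSTROM)
            times.append(float(ts.time) if ts.time is not None else float(ts.frame))
    return FrameEnsemble(topology, np.array(frames), np.array(times))


def _empty_universe(topology: Topology):
    import MDAnalysis as mda

    n = topology.n_atoms
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=topology.n_residues,
        n_segments=len(np.unique(topology.chains)),
        atom_resindex=topology.resindices,
        residue_segindex=_segindex(topology),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.atom_names.tolist())
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resids", topology.resids.tolist())
    u.add_TopologyAttr("resnames", topology.resnames.tolist())
    u.add_TopologyAttr("segids", [str(c) for c in np.unique(topology.chains)])
    u.add_TopologyAttr("chainIDs", [str(c) for c in topology.atom_chains])
    return u


def _segindex(topology: Topology) -> np.ndarray:
    uniq = {c: i for i, c in enumerate(np.unique(topology.chains))}
    return np.array([uniq[c] for c in topology.chains], dtype=np.intp)


def _box_for(coords: np.ndarray) -> np.ndarray:
    span = (coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))).max() + 4.0  # nm
    edge = max(span, 10.0) / _NM_PER_ANGSTROM
    return np.array([edge, edge, edge, 90.0, 90.0, 90.0])


def write_structure(ensemble: FrameEnsemble, path: str, frame: int = 0) -> None:
    """Write one frame as PDB or GRO (chosen by file suffix)."""
    import MDAnalysis as mda

    u = _empty_universe(ensemble.topology)
    u.atoms.positions = ensemble.coords[frame] / _NM_PER_ANGSTROM
    u.dimensions = _box_for(ensemble.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_trajectory(ensemble: FrameEnsemble, path: str) -> None:
    """Write all frames as XTC, DCD or multi-model PDB (chosen by suffix)."""
    import MDAnalysis as mda

    u = _empty_universe(ensemble.topology)
    u.dimensions = _box_for(ensemble.coords)
    box = _box_for(ensemble.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=ensemble.n_atoms) as w:
            for f in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coords[f] / _NM_PER_ANGSTROM
                ts = u.trajectory.ts
                ts.frame = f
                ts.dimensions = box
                if ensemble.times is not None:
                    ts.time = float(ensemble.times[f])
                w.write(u.atoms)
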