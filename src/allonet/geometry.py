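"""Order parameters and dimensionality reduction for coordinate ensembles.

Implements the scalar descriptors used to characterize chaperone NBD
dynamics — the inter-subdomain pseudo-torsion (dihedral of four group
centres of mass), atom dihedrals, centre-of-mass and minimum distances,
antiparallel β-sheet content via template RMSD with a rational switching
function, and PCA of backbone coordinate covariance — plus the small
statistics helpers (squared Pearson correlation, normalized histograms)
used to relate them.

Angles are reported in degrees in (−180°, 180°]; distances in nm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .model import AtomSelection, FrameEnsemble, Topology, kabsch

__all__ = [
    "OrderParameterSeries",
    "PCAResult",
    "BetaContentParams",
    "dihedral",
    "subdomain_torsion",
    "group_distance",
    "beta_content",
    "pca",
    "correlate",
    "histogram",
    "center_of_mass",
    "load_antibeta_template",
]


@dataclass
class OrderParameterSeries:
    """A named per-frame scalar series with units (deg, nm or dimensionless)."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str, times: Optional[np.ndarray] = None) -> None:
        t = np.arange(len(self.values)) if times is None else times
        header = f"frame\t{self.name}_{self.units}"
        np.savetxt(path, np.column_stack([t, self.values]), header=header,
                   delimiter="\t", comments="")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "units": self.units,
                       "values": self.values.tolist()}, fh)


# ---------------------------------------------------------------------------
# Dihedrals and distances
# ---------------------------------------------------------------------------

def dihedral_from_points(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral (degrees) of four points; inputs broadcast over frames."""
    p1, p2, p3, p4 = (np.atleast_2d(np.asarray(p)) for p in (p1, p2, p3, p4))
    u1 = p2 - p1
    u2 = p3 - p2
    u3 = p4 - p3
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    norm_u2 = np.linalg.norm(u2, axis=-1)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-12) or np.any(np.linalg.norm(n2, axis=-1) < 1e-12):
        raise ValueError("collinear atoms: dihedral undefined")
    x = (n1 * n2).sum(axis=-1) * norm_u2
    y = (np.cross(n1, n2) * u2).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # canonical range (−180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def dihedral(ensemble: FrameEnsemble, atoms: Sequence[int], name: str = "dihedral") -> OrderParameterSeries:
    """Per-frame signed dihedral of four atoms, in degrees."""
    atoms = list(atoms)
    if len(atoms) != 4 or len(set(atoms)) != 4:
        raise ValueError("dihedral requires four distinct atom indices")
    c = ensemble.coords[:, atoms, :]
    vals = dihedral_from_points(c[:, 0], c[:, 1], c[:, 2], c[:, 3])
    return OrderParameterSeries(name, vals, "deg")


def center_of_mass(ensemble: FrameEnsemble, selection: AtomSelection,
                   mass_weighted: bool = True) -> np.ndarray:
    """(F, 3) centre of the selection; mass-weighted when masses are known."""
    selection.require_nonempty()
    idx = selection.indices
    coords = ensemble.coords[:, idx, :]
    if mass_weighted:
        m = ensemble.topology.masses[idx]
        if m.sum() > 0:
            return (coords * m[None, :, None]).sum(axis=1) / m.sum()
    return coords.mean(axis=1)


def subdomain_torsion(ensemble: FrameEnsemble, groups: Sequence[AtomSelection],
                      name: str = "subdomain_torsion",
                      mass_weighted: bool = True) -> OrderParameterSeries:
    """Pseudo-dihedral of the four group centres of mass, in degrees.

    The canonical use is the inter-lobe rotation of an Hsp70 NBD, with the
    groups being the backbone atoms of lobes IB, IA, IIA and IIB.
    """
    if len(groups) != 4:
        raise ValueError("subdomain torsion requires exactly four atom groups")
    coms = [center_of_mass(ensemble, g, mass_weighted) for g in groups]
    for a, b in zip(coms[:-1], coms[1:]):
        if np.any(np.linalg.norm(a - b, axis=-1) < 1e-9):
            raise ValueError("coincident consecutive group centres of mass")
    vals = dihedral_from_points(*coms)
    return OrderParameterSeries(name, vals, "deg")


def group_distance(ensemble: FrameEnsemble, a: AtomSelection, b: AtomSelection,
                   mode: str = "com", name: str = "distance",
                   mass_weighted: bool = True) -> OrderParameterSeries:
    """Per-frame COM–COM distance or minimum cross-pair distance, in nm."""
    a.require_nonempty()
    b.require_nonempty()
    if mode == "com":
        ca = center_of_mass(ensemble, a, mass_weighted)
        cb = center_of_mass(ensemble, b, mass_weighted)
        vals = np.linalg.norm(ca - cb, axis=-1)
    elif mode == "min":
        pa = ensemble.coords[:, a.indices, :]
        pb = ensemble.coords[:, b.indices, :]
        diff = pa[:, :, None, :] - pb[:, None, :, :]
        vals = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return OrderParameterSeries(name, vals, "nm")


# ---------------------------------------------------------------------------
# Antiparallel beta-sheet content
# ---------------------------------------------------------------------------

_BETA_ATOMS = ("N", "CA", "CB", "C", "O")


@dataclass
class BetaContentParams:
    """Parameters of the antiparallel β-content collective variable.

    ``segment_a``/``segment_b`` are consecutive source-numbered residue ids of
    the two strand regions.  Every ordered pair of 3-residue windows (one per
    segment) whose window centres lie within ``strands_cutoff_nm`` contributes
    ``(1 − x^n)/(1 − x^m)`` with ``x = (r − d0)/r0`` and ``r`` the optimal
    superposition RMSD of the 30-atom block onto the packaged idealized
    antiparallel two-strand backbone template.
    """

    segment_a: Sequence[int] = ()
    segment_b: Sequence[int] = ()
    r0_nm: float = 0.08
    n_exp: int = 8
    m_exp: int = 12
    d0_nm: float = 0.0
    strands_cutoff_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.r0_nm <= 0:
            raise ValueError("r0 must be positive")
        if self.n_exp >= self.m_exp:
            raise ValueError("switching exponents require n < m")


def load_antibeta_template() -> np.ndarray:
    """Load the packaged 30-atom antiparallel template block, (6, 5, 3) nm.

    The template is an idealized, synthetic two-strand antiparallel backbone
    block (residues of the second strand listed in ascending sequence order,
    running spatially antiparallel to the first), pinned as a versioned data
    file so β-content values are reproducible.
    """
    ref = resources.files("allonet.data").joinpath("antibeta_template.tsv")
    rows = np.loadtxt(str(ref), skiprows=1, usecols=(2, 3, 4))
    if rows.shape != (30, 3):
        raise ValueError("antiparallel template must contain 30 atoms")
    return rows.reshape(6, 5, 3)


def switching_function(r: float, r0: float, n: int, m: int, d0: float = 0.0) -> float:
    """Rational switching (1 − x^n)/(1 − x^m); continuous limit n/m at x = 1."""
    x = (r - d0) / r0
    if abs(x - 1.0) < 1e-9:
        return n / m
    if x < 0:
        x = 0.0
    return (1.0 - x ** n) / (1.0 - x ** m)


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral virtual CB for glycine, from backbone N, CA, C."""
    b1 = ca - n
    b2 = ca - c
    bisector = b1 + b2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    direction = 0.817 * bisector + 0.577 * perp
    direction /= np.linalg.norm(direction)
    return ca + 0.153 * direction


def _residue_beta_atoms(topology: Topology, coords: np.ndarray, resid: int) -> np.ndarray:
    """(5, 3) N/CA/CB/C/O coordinates of one residue in one frame."""
    mask = topology.atom_resids == resid
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"residue {resid} not in topology")
    names = {topology.atom_names[i]: i for i in idx}
    out = np.empty((5, 3))
    for k, atom in enumerate(_BETA_ATOMS):
        if atom in names:
            out[k] = coords[names[atom]]
        elif atom == "CB":
            for need in ("N", "CA", "C"):
                if need not in names:
                    raise ValueError(f"residue {resid} lacks backbone atom {need}")
            out[k] = _virtual_cb(coords[names["N"]], coords[names["CA"]], coords[names["C"]])
        else:
            raise ValueError(f"residue {resid} lacks backbone atom {atom}")
    return out


def beta_content(ensemble: FrameEnsemble, params: BetaContentParams,
                 name: str = "beta_content") -> OrderParameterSeries:
    """Antiparallel β-sheet content *s* per frame.

    Sums the switching function of the template RMSD over all eligible
    3+3-residue window pairs between the two strand segments.
    """
    seg_a = list(params.segment_a)
    seg_b = list(params.segment_b)
    if len(seg_a) < 3 or len(seg_b) < 3:
        raise ValueError("each strand segment must contain at least 3 residues")
    template = load_antibeta_template().reshape(30, 3)
    top = ensemble.topology
    windows_a = [seg_a[i:i + 3] for i in range(len(seg_a) - 2)]
    windows_b = [seg_b[i:i + 3] for i in range(len(seg_b) - 2)]
    values = np.zeros(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        coords = ensemble.coords[f]
        res_atoms = {r: _residue_beta_atoms(top, coords, r) for r in set(seg_a) | set(seg_b)}
        s = 0.0
        for wa in windows_a:
            center_a = res_atoms[wa[1]][1]  # CA of middle residue
            for wb in windows_b:
                center_b = res_atoms[wb[1]][1]
                if np.linalg.norm(center_a - center_b) > params.strands_cutoff_nm:
                    continue
                block = np.concatenate([res_atoms[r] for r in wa + wb])
                R, t = kabsch(block, template)
                fitted = block @ R.T + t
                r = float(np.sqrt(((fitted - template) ** 2).sum() / 30.0))
                s += switching_function(r, params.r0_nm, params.n_exp, params.m_exp,
                                        params.d0_nm)
        values[f] = s
    return OrderParameterSeries(name, values, "dimensionless")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigendecomposition of the 3A×3A coordinate covariance of a fit selection."""

    eigenvalues: np.ndarray            # all, descending, nm^2
    variance_fractions: np.ndarray     # all, sums to 1
    mean: np.ndarray                   # (3A,) nm
    components: np.ndarray             # (n_components, 3A), orthonormal rows
    fit_indices: np.ndarray            # atom indices the decomposition was fit on
    projections: np.ndarray            # (F, n_components) of the fit ensemble

    def project(self, ensemble: FrameEnsemble) -> np.ndarray:
        """Project another ensemble (same topology/atom order) onto the components."""
        flat = ensemble.coords[:, self.fit_indices, :].reshape(ensemble.n_frames, -1)
        return (flat - self.mean) @ self.components.T

    def export_components(self, path: str, selection_label: str = "") -> None:
        header = f"pca_components fit={selection_label} rows=components cols=3A"
        np.savetxt(path, self.components, header=header, delimiter="\t")


def pca(ensemble: FrameEnsemble, fit: AtomSelection, n_components: int = 5) -> PCAResult:
    """PCA of coordinate covariance about the ensemble mean over ``fit`` atoms.

    The ensemble should already be superposed on the fit selection.  When
    comparing two systems, fit on their concatenation (merged-ensemble mean)
    and project each system with :meth:`PCAResult.project`.
    """
    fit.require_nonempty()
    if ensemble.n_frames < 2:
        raise ValueError("PCA requires at least two frames")
    flat = ensemble.coords[:, fit.indices, :].reshape(ensemble.n_frames, -1)
    if ensemble.n_frames < 3 * len(fit.indices):
        warnings.warn(
            "fewer frames than 3x fit atoms: PCA eigenvalues will be noisy",
            stacklevel=2,
        )
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (ensemble.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    fractions = evals / evals.sum() if evals.sum() > 0 else evals
    n_components = min(n_components, len(evals))
    components = evecs[:, :n_components].T
    projections = centered @ components.T
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        mean=mean,
        components=components,
        fit_indices=fit.indices.copy(),
        projections=projections,
    )


# ---------------------------------------------------------------------------
# Statistics helpers
# ---------------------------------------------------------------------------

def correlate(series_a: OrderParameterSeries, series_b: OrderParameterSeries) -> float:
    """Squared Pearson correlation R² between two equal-length series."""
    a = series_a.values
    b = series_b.values
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def histogram(series: OrderParameterSeries, bins) -> tuple[np.ndarray, np.ndarray]:
    """Probability density over the given bin edges; integrates to 1."""
    if len(series.values) == 0:
        raise ValueError("empty series")
    density, edges = np.histogram(series.values, bins=bins, density=True)
    if not np.isfinite(density).all() or density.sum() == 0:
        raise ValueError("no values fall inside the histogram range")
    return edges, density
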