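"""Synthetic inputs with machine-readable ground truth.

Every input class the analysis stages consume can be generated here with a
known answer attached, so the whole pipeline is testable without external
downloads:

* bead-chain coordinate ensembles with a *planted* chain of correlated
  residues (a known allosteric path) or a planted two-block correlation
  structure (known communities), sampled from an explicit multivariate
  Gaussian;
* umbrella-sampling window series drawn from the Boltzmann distribution of a
  known 1-D potential under harmonic biases (direct Gaussian sampling for
  harmonic potentials, a thinned Metropolis chain otherwise), with the
  analytic PMF tabulated alongside;
* scripted contact-geometry ensembles whose residue pairs satisfy or violate
  each typed contact criterion by construction;
* exact geometry fixtures (dihedrals, four-group pseudo-torsions, an ideal
  antiparallel hairpin, a coil).

These are statistical and geometric stand-ins, not models of real protein
dynamics; their defaults mirror the study conditions stated in the package
documentation.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .free_energy import KB_KJ_PER_MOL_K, UmbrellaDataset, UmbrellaWindow
from .geometry import dihedral_from_points, load_antibeta_template
from .model import FrameEnsemble, Topology

__all__ = [
    "GroundTruth",
    "EnsembleSpec",
    "PartitionSpec",
    "UmbrellaSpec",
    "ContactScriptEntry",
    "make_planted_network_ensemble",
    "make_planted_partition_ensemble",
    "make_umbrella_dataset",
    "make_contact_script_ensemble",
    "make_geometry_fixture",
    "helix_layout",
]


@dataclass
class GroundTruth:
    """What the generator planted, in the terms the downstream stage is scored in."""

    planted_path: Optional[list[int]] = None          # source-numbered resids, ordered
    planted_partition: Optional[dict[int, int]] = None  # resid -> community label
    analytic_pmf: Optional[tuple[np.ndarray, np.ndarray]] = None  # (xi grid nm, G in kT)
    scripted_contacts: Optional[dict] = None          # (resid_i, resid_j) -> (type, freq)

    def __post_init__(self) -> None:
        if (self.planted_path is None and self.planted_partition is None
                and self.analytic_pmf is None and self.scripted_contacts is None):
            raise ValueError("ground truth must populate at least one field")
        if self.analytic_pmf is not None:
            grid, g = self.analytic_pmf
            if np.any(np.diff(grid) <= 0):
                raise ValueError("analytic PMF grid must be strictly increasing")

    def to_json(self, path: str) -> None:
        payload = {
            "planted_path": self.planted_path,
            "planted_partition": (
                {str(k): int(v) for k, v in self.planted_partition.items()}
                if self.planted_partition else None),
            "analytic_pmf": (
                {"xi_nm": self.analytic_pmf[0].tolist(),
                 "g_kt": self.analytic_pmf[1].tolist()}
                if self.analytic_pmf else None),
            "scripted_contacts": (
                [{"resid_i": int(i), "resid_j": int(j), "type": t, "frequency": f}
                 for (i, j), (t, f) in self.scripted_contacts.items()]
                if self.scripted_contacts else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Bead-chain ensembles with planted correlation structure
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Planted-path bead-chain ensemble specification.

    ``source``/``sink`` are source-numbered residue ids; ``n_intermediates``
    residues are planted evenly between them, and consecutive planted residues
    are coupled with per-dimension correlation ``rho`` (decaying as ρ^|lag|
    along the planted chain so the covariance stays positive definite).
    """

    n_residues: int = 30
    n_frames: int = 5000
    sigma_nm: float = 0.02
    source: int = 5
    sink: int = 25
    n_intermediates: int = 4
    rho: float = 0.8
    background_rho: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.n_frames < 100:
            raise ValueError("n_frames must be at least 100")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def planted_resids(self) -> list[int]:
        steps = np.linspace(self.source, self.sink, self.n_intermediates + 2)
        resids = [int(round(s)) for s in steps]
        if len(set(resids)) != len(resids):
            raise ValueError("planted chain residues are not distinct")
        return resids


@dataclass
class PartitionSpec:
    """Planted two-block ensemble: equicorrelated blocks, independent across.

    Beads sit on a compact spherical shell so that *every* pair is a
    persistent contact — the graph topology is a complete graph and carries
    no information.  Community recovery must therefore come entirely from
    the generalized-correlation edge weights, which is the property under
    test.
    """

    n_residues: int = 20
    n_frames: int = 1000
    sigma_nm: float = 0.02
    rho_in: float = 0.5
    background_rho: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_in < 1:
            raise ValueError("rho_in must lie in [0, 1)")
        if self.n_frames < 100:
            raise ValueError("n_frames must be at least 100")


def helix_layout(n_residues: int, radius: float = 0.28, pitch: float = 0.38,
                 per_turn: int = 4) -> np.ndarray:
    """Compact helical bead layout, (n, 3) nm.

    With 4 beads per turn, consecutive beads sit ~0.41 nm apart and beads four
    apart sit one pitch (~0.38 nm) apart, so both |i−j| = 1 and |i−j| = 4
    pairs fall under a 0.45 nm contact cutoff while all other pairs (the
    nearest, |i−j| = 3, at ~0.49 nm) stay outside it — a chain topology rich
    enough to carry non-trivial shortest paths.
    """
    i = np.arange(n_residues)
    theta = 2 * np.pi * i / per_turn
    return np.column_stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        pitch * i / per_turn,
    ])


def _bead_topology(n_residues: int) -> Topology:
    return Topology.from_atom_records(
        atom_names=["CA"] * n_residues,
        resids=list(range(1, n_residues + 1)),
        resnames=["ALA"] * n_residues,
    )


def _sample_correlated_ensemble(base: np.ndarray, corr: np.ndarray, sigma: float,
                                n_frames: int, seed: int) -> np.ndarray:
    """Frames = base + displacements with per-dimension correlation ``corr``."""
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "planted correlation matrix is not positive definite; lower rho"
        ) from exc
    rng = np.random.default_rng(seed)
    n = base.shape[0]
    z = rng.standard_normal((n_frames, 3, n))
    disp = sigma * np.einsum("ij,fdj->fdi", L, z)      # (F, 3, n)
    return base[None, :, :] + np.transpose(disp, (0, 2, 1))


def make_planted_network_ensemble(spec: EnsembleSpec
                                  ) -> tuple[Topology, FrameEnsemble, GroundTruth]:
    """Bead-chain ensemble with a planted chain of correlated residues."""
    top = _bead_topology(spec.n_residues)
    base = helix_layout(spec.n_residues)
    corr = np.eye(spec.n_residues)
    for i in range(spec.n_residues - 1):
        corr[i, i + 1] = corr[i + 1, i] = spec.background_rho
    planted = spec.planted_resids()
    planted_idx = [r - 1 for r in planted]
    for a in range(len(planted_idx)):
        for b in range(a + 1, len(planted_idx)):
            rho_ab = spec.rho ** (b - a)
            corr[planted_idx[a], planted_idx[b]] = rho_ab
            corr[planted_idx[b], planted_idx[a]] = rho_ab
    coords = _sample_correlated_ensemble(base, corr, spec.sigma_nm,
                                         spec.n_frames, spec.seed)
    ens = FrameEnsemble(top, coords, times=np.arange(spec.n_frames, dtype=float))
    return top, ens, GroundTruth(planted_path=planted)


def blob_layout(n_residues: int, radius: float = 0.17) -> np.ndarray:
    """Fibonacci-sphere bead layout, (n, 3) nm.

    All beads lie within 2*radius (~0.34 nm) of each other, so every pair is
    a persistent contact under a 0.45 nm cutoff: a complete, uninformative
    contact graph.
    """
    i = np.arange(n_residues)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n_residues
    r = np.sqrt(1.0 - y * y)
    return radius * np.column_stack([r * np.cos(golden * i), y,
                                     r * np.sin(golden * i)])


def make_planted_partition_ensemble(spec: PartitionSpec
                                    ) -> tuple[Topology, FrameEnsemble, GroundTruth]:
    """Compact-blob ensemble whose first/second halves form two correlation blocks."""
    n = spec.n_residues
    half = n // 2
    top = _bead_topology(n)
    base = blob_layout(n)
    corr = np.eye(n)
    for i in range(n - 1):
        corr[i, i + 1] = corr[i + 1, i] = spec.background_rho
    for block in (range(half), range(half, n)):
        block = list(block)
        for a in block:
            for b in block:
                if a < b:
                    corr[a, b] = corr[b, a] = max(spec.rho_in, corr[a, b])
    coords = _sample_correlated_ensemble(base, corr, spec.sigma_nm,
                                         spec.n_frames, spec.seed)
    ens = FrameEnsemble(top, coords, times=np.arange(spec.n_frames, dtype=float))
    partition = {r: (0 if r <= half else 1) for r in range(1, n + 1)}
    return top, ens, GroundTruth(planted_partition=partition)


# ---------------------------------------------------------------------------
# Umbrella-sampling datasets from known potentials
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaSpec:
    """Biased sampling of a known 1-D potential under a harmonic window ladder.

    Defaults mirror the umbrella layout used for the T199–γ-phosphate
    coordinate: ten equally spaced windows spanning 0.3–1.2 nm with a
    1500 kJ·mol⁻¹·nm⁻² spring at 310 K.
    """

    potential: str = "harmonic"                  # "harmonic" | "double_well" | "flat"
    params: dict = field(default_factory=lambda: {"kappa": 100.0, "xi0": 0.6})
    windows: Sequence[float] = tuple(np.linspace(0.3, 1.2, 10).round(6))
    spring_constant: float = 1500.0              # kJ/mol/nm^2
    n_samples: int = 5000
    temperature: float = 310.0
    seed: int = 0
    n_chains: int = 25                           # parallel Metropolis chains
    burn_in: int = 1000
    thinning: int = 20

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("window centers must be sorted and distinct")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.n_samples < 100:
            raise ValueError("n_samples must be at least 100")

    def potential_energy(self, xi: np.ndarray) -> np.ndarray:
        """U(ξ) in kJ/mol."""
        xi = np.asarray(xi, dtype=float)
        if self.potential == "harmonic":
            kappa = self.params["kappa"]
            xi0 = self.params["xi0"]
            return 0.5 * kappa * (xi - xi0) ** 2
        if self.potential == "double_well":
            a, b = self.params["minima"]
            h = self.params["barrier"]            # kJ/mol at the midpoint
            mid = 0.5 * (a + b)
            w = 0.5 * (b - a)
            return h * ((xi - mid) ** 2 - w ** 2) ** 2 / w ** 4
        if self.potential == "flat":
            return np.zeros_like(xi)
        raise ValueError(f"unknown potential {self.potential!r}")


def _metropolis_window(spec: UmbrellaSpec, center: float, kbt: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Thinned Metropolis sampling of exp(−[U+bias]/kT) via parallel chains."""
    k = spec.spring_constant
    n_chains = spec.n_chains
    kept_per_chain = int(np.ceil(spec.n_samples / n_chains))
    step = 1.2 * np.sqrt(kbt / k)

    def energy(x):
        return spec.potential_energy(x) + 0.5 * k * (x - center) ** 2

    x = center + rng.normal(0, np.sqrt(kbt / k), n_chains)
    e = energy(x)
    accepted = 0
    total = 0
    kept = []
    n_steps = spec.burn_in + kept_per_chain * spec.thinning
    for s in range(n_steps):
        prop = x + rng.normal(0, step, n_chains)
        ep = energy(prop)
        accept = rng.random(n_chains) < np.exp(np.minimum(0.0, -(ep - e) / kbt))
        x = np.where(accept, prop, x)
        e = np.where(accept, ep, e)
        accepted += int(accept.sum())
        total += n_chains
        if s >= spec.burn_in and (s - spec.burn_in) % spec.thinning == spec.thinning - 1:
            kept.append(x.copy())
    if accepted / total < 0.05:
        raise ValueError(
            f"Metropolis acceptance {accepted / total:.3f} < 5% in window at "
            f"{center:.3f} nm; the potential/bias scales look wrong"
        )
    samples = np.array(kept)                      # (kept_per_chain, n_chains)
    lag1 = np.mean([np.corrcoef(samples[:-1, c], samples[1:, c])[0, 1]
                    for c in range(n_chains)])
    if lag1 > 0.1:
        raise ValueError(
            f"lag-1 autocorrelation {lag1:.3f} of thinned samples exceeds 0.1; "
            "increase thinning"
        )
    return samples.T.reshape(-1)[: spec.n_samples]


def make_umbrella_dataset(spec: UmbrellaSpec) -> tuple[UmbrellaDataset, GroundTruth]:
    """Sample every window of the ladder; tabulate the analytic min-anchored PMF."""
    kbt = KB_KJ_PER_MOL_K * spec.temperature
    rng = np.random.default_rng(spec.seed)
    windows = []
    for center in spec.windows:
        if spec.potential in ("harmonic", "flat"):
            kappa = spec.params.get("kappa", 0.0) if spec.potential == "harmonic" else 0.0
            xi0 = spec.params.get("xi0", 0.0)
            prec = (kappa + spec.spring_constant) / kbt
            mean = (kappa * xi0 + spec.spring_constant * center) / (kappa + spec.spring_constant)
            xi = rng.normal(mean, 1.0 / np.sqrt(prec), spec.n_samples)
        else:
            xi = _metropolis_window(spec, center, kbt, rng)
        windows.append(UmbrellaWindow(center, spec.spring_constant, xi,
                                      time=np.arange(spec.n_samples, dtype=float)))
    dataset = UmbrellaDataset(windows, spec.temperature)
    lo, hi = float(spec.windows[0]), float(spec.windows[-1])
    if hi <= lo:  # single window: tabulate around its sampled range
        spread = 3.0 * np.sqrt(kbt / spec.spring_constant)
        lo, hi = lo - spread, hi + spread
    grid = np.linspace(lo, hi, 241)
    u = spec.potential_energy(grid)
    g_kt = (u - u.min()) / kbt
    return dataset, GroundTruth(analytic_pmf=(grid, g_kt))


# ---------------------------------------------------------------------------
# Scripted contact-geometry ensembles
# ---------------------------------------------------------------------------

CONTACT_TAGS = ("hbond_pass", "hbond_fail_angle", "ionic", "pi_stack",
                "pi_cation", "hydrophobic")

_TAG_TYPE = {
    "hbond_pass": ("hbond", True),
    "hbond_fail_angle": ("hbond", False),
    "ionic": ("ionic", True),
    "pi_stack": ("pi_stack", True),
    "pi_cation": ("pi_cation", True),
    "hydrophobic": ("hydrophobic", True),
}


@dataclass
class ContactScriptEntry:
    """One scripted residue pair: geometry ``tag`` realized in ``contact_frames``."""

    tag: str
    contact_frames: Sequence[int]
    distance_nm: Optional[float] = None   # override of the key heavy-atom distance

    def __post_init__(self) -> None:
        if self.tag not in CONTACT_TAGS:
            raise ValueError(f"unknown geometry tag {self.tag!r}")


def _ring(center: np.ndarray, normal: np.ndarray, radius: float = 0.139) -> np.ndarray:
    """Six-membered ring coordinates around ``center`` with the given normal."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.arange(6) * np.pi / 3
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def _entry_atoms(entry: ContactScriptEntry, origin: np.ndarray, in_contact: bool):
    """Atom records and coordinates for one scripted pair.

    Returns (records_a, records_b, coords_a, coords_b); records are
    (atom_name, resname) tuples.  The second residue is displaced by 2 nm when
    the frame is out of contact.
    """
    tag = entry.tag
    d = entry.distance_nm
    shift = np.array([0.0, 2.0, 0.0]) if not in_contact else 0.0

    if tag in ("hbond_pass", "hbond_fail_angle"):
        dist = 0.29 if d is None else d
        a = [("CB", "SER"), ("OG", "SER"), ("HG", "SER")]
        ca = np.array([[-0.15, 0.0, 0.0], [0.0, 0.0, 0.0], [0.10, 0.0, 0.0]])
        b = [("CG", "ASN"), ("OD1", "ASN")]
        if tag == "hbond_pass":
            acc = np.array([dist, 0.0, 0.0])
        else:
            # 140 degrees at the hydrogen: D->H along +x, H->A rotated 40 deg off +x
            direction = np.array([np.cos(np.radians(40.0)), np.sin(np.radians(40.0)), 0.0])
            acc = np.array([0.10, 0.0, 0.0]) + 0.18 * direction
        cb = np.array([acc + np.array([0.12, 0.05, 0.0]), acc])  # CG, then OD1 at acc
    elif tag == "ionic":
        dist = 0.35 if d is None else d
        a = [("CG", "ASP"), ("OD1", "ASP"), ("OD2", "ASP")]
        ca = np.array([[-0.12, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.06, 0.11, 0.0]])
        b = [("CE", "LYS"), ("NZ", "LYS")]
        cb = np.array([[dist + 0.15, 0.0, 0.0], [dist, 0.0, 0.0]])
    elif tag == "pi_stack":
        dist = 0.45 if d is None else d
        ring_a = _ring(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        ring_b = _ring(np.array([0.0, 0.0, dist]), np.array([0.0, 0.0, 1.0]))
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        a = [(n, "PHE") for n in names]
        b = [(n, "PHE") for n in names]
        ca, cb = ring_a, ring_b
    elif tag == "pi_cation":
        dist = 0.40 if d is None else d
        ring_a = _ring(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        a = [(n, "PHE") for n in ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]]
        b = [("CE", "LYS"), ("NZ", "LYS")]
        ca = ring_a
        cb = np.array([[0.0, 0.0, dist + 0.15], [0.0, 0.0, dist]])
    elif tag == "hydrophobic":
        dist = 0.37 if d is None else d   # Bondi C+C (0.34) + 0.03 margin
        a = [("CD1", "LEU")]
        b = [("CG1", "VAL")]
        ca = np.array([[0.0, 0.0, 0.0]])
        cb = np.array([[dist, 0.0, 0.0]])
    else:  # pragma: no cover
        raise ValueError(tag)
    return a, b, origin + ca, origin + cb + shift


def make_contact_script_ensemble(script: Sequence[ContactScriptEntry], n_frames: int = 4
                                 ) -> tuple[Topology, FrameEnsemble, GroundTruth]:
    """Build an ensemble realizing each scripted contact geometry exactly.

    Each entry occupies its own residue pair, widely separated from other
    entries; the pair is in its tagged geometry during ``contact_frames`` and
    displaced apart otherwise.  The expected frequency (0 for
    criterion-violating tags) is recorded as ground truth.
    """
    names, resids, resnames = [], [], []
    pair_resids = []
    rid = 0
    for entry in script:
        for frame in entry.contact_frames:
            if not 0 <= frame < n_frames:
                raise ValueError("scripted frame outside ensemble range")
        rec_a, rec_b, _, _ = _entry_atoms(entry, np.zeros(3), True)
        rid += 1
        ra = rid
        for atom, res in rec_a:
            names.append(atom); resids.append(ra); resnames.append(res)
        rid += 2  # sequence gap: scripted pairs are never sequence neighbours
        rb = rid
        for atom, res in rec_b:
            names.append(atom); resids.append(rb); resnames.append(res)
        rid += 1
        pair_resids.append((ra, rb))
    top = Topology.from_atom_records(names, resids, resnames)

    coords = np.zeros((n_frames, top.n_atoms, 3))
    truth = {}
    for f in range(n_frames):
        pos = 0
        for e_idx, entry in enumerate(script):
            origin = np.array([0.0, 0.0, 4.0 * e_idx])
            in_contact = f in set(entry.contact_frames)
            rec_a, rec_b, ca, cb = _entry_atoms(entry, origin, in_contact)
            na, nb = len(rec_a), len(rec_b)
            coords[f, pos:pos + na] = ca
            coords[f, pos + na:pos + na + nb] = cb
            pos += na + nb
    for entry, (ra, rb) in zip(script, pair_resids):
        ctype, passes = _TAG_TYPE[entry.tag]
        freq = len(set(entry.contact_frames)) / n_frames if passes else 0.0
        truth[(ra, rb)] = (ctype, freq)
    ens = FrameEnsemble(top, coords, times=np.arange(n_frames, dtype=float))
    return top, ens, GroundTruth(scripted_contacts=truth)


# ---------------------------------------------------------------------------
# Exact geometry fixtures
# ---------------------------------------------------------------------------

def _dihedral_points(angle_deg: float, bond: float = 0.15, arm: float = 0.10) -> np.ndarray:
    """Four points whose signed dihedral equals ``angle_deg`` exactly."""
    phi = np.radians(angle_deg)
    return np.array([
        [0.0, arm, 0.0],
        [0.0, 0.0, 0.0],
        [bond, 0.0, 0.0],
        [bond, arm * np.cos(phi), arm * np.sin(phi)],
    ])


def make_geometry_fixture(kind: str, angle_deg: Optional[float] = None
                          ) -> tuple[Topology, FrameEnsemble]:
    """Single-frame fixtures with exactly known geometry.

    ``dihedral``: four atoms with the requested signed dihedral.
    ``lobe_torsion``: four 3-atom rigid groups whose centres of mass realize
    the requested pseudo-dihedral (residues 1–4, selectable by resid).
    ``ideal_hairpin``: the packaged antiparallel template as a 6-residue
    structure (β-content scores its single eligible block at RMSD 0).
    ``coil``: 6 extended residues far from the antiparallel template.
    """
    if kind == "dihedral":
        if angle_deg is None:
            raise ValueError("dihedral fixture requires an angle")
        if not -180.0 < angle_deg <= 180.0:
            raise ValueError("angle must lie in (-180, 180]")
        pts = _dihedral_points(angle_deg)
        top = Topology.from_atom_records(["C1", "C2", "C3", "C4"],
                                         [1, 2, 3, 4], ["UNK"] * 4)
        ens = FrameEnsemble(top, pts[None])
        assert abs(dihedral_from_points(*pts)[0] - angle_deg) < 1e-9 or abs(angle_deg) == 180.0
        return top, ens
    if kind == "lobe_torsion":
        if angle_deg is None:
            raise ValueError("lobe_torsion fixture requires an angle")
        centers = _dihedral_points(angle_deg, bond=1.5, arm=1.0)
        offsets = np.array([[0.05, 0.0, 0.0], [-0.05, 0.0, 0.0], [0.0, 0.0, 0.0]])
        names, resids, resnames, coords = [], [], [], []
        for r, c in enumerate(centers, start=1):
            for k, off in enumerate(offsets, start=1):
                names.append(f"C{k}")
                resids.append(r)
                resnames.append("UNK")
                coords.append(c + off)
        top = Topology.from_atom_records(names, resids, resnames)
        return top, FrameEnsemble(top, np.array(coords)[None])
    if kind in ("ideal_hairpin", "coil"):
        if kind == "ideal_hairpin":
            block = load_antibeta_template()          # (6, 5, 3)
        else:
            block = np.zeros((6, 5, 3))
            for r in range(6):
                x0 = 0.35 * r
                block[r] = [[x0 - 0.12, 0.05, 0.0], [x0, 0.0, 0.0],
                            [x0, -0.15, 0.0], [x0 + 0.12, 0.05, 0.0],
                            [x0 + 0.14, 0.17, 0.0]]
        names, resids, resnames, coords = [], [], [], []
        for r in range(6):
            for k, atom in enumerate(("N", "CA", "CB", "C", "O")):
                names.append(atom)
                resids.append(r + 1)
                resnames.append("ALA")
                coords.append(block[r, k])
        top = Topology.from_atom_records(names, resids, resnames)
        return top, FrameEnsemble(top, np.array(coords)[None])
    raise ValueError(f"unknown fixture kind {kind!r}")
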