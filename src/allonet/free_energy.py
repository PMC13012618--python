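"""Free-energy profiles from umbrella-sampling time series.

Reconstructs the potential of mean force G(ξ) along a reaction coordinate
from harmonically biased window samples with the weighted histogram analysis
method (WHAM), solved by self-consistent iteration in log space.  Errors
come from a moving-block bootstrap whose block length is set by the
integrated autocorrelation time of each window's series, so correlated
samples are not treated as independent.  Convergence against trajectory
length and state free-energy differences (e.g. between a "close" and a
"far" conformational state along the coordinate) are provided on top.

Units: reaction coordinate in nm, spring constants in kJ·mol⁻¹·nm⁻²,
temperature in K.  Profiles are computed in kT and reported in kcal/mol
(kB = 0.008314 kJ·mol⁻¹·K⁻¹, 1 kcal = 4.184 kJ).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB_KJ_PER_MOL_K",
    "KCAL_PER_KJ",
    "UmbrellaWindow",
    "UmbrellaDataset",
    "FreeEnergyProfile",
    "StateDefinition",
    "wham",
    "bootstrap_error",
    "convergence_profile",
    "delta_g",
    "integrated_autocorrelation_time",
    "load_umbrella_dataset",
    "write_umbrella_dataset",
]

KB_KJ_PER_MOL_K = 0.008314
KCAL_PER_KJ = 1.0 / 4.184


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint ½k(ξ−ξ₀)² plus its sample series."""

    center: float                      # nm
    spring_constant: float             # kJ/mol/nm^2
    xi: np.ndarray                     # (n,) nm
    time: Optional[np.ndarray] = None  # (n,) ps
    one_sided: bool = False            # pulling-style restraint; excluded from WHAM

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if len(self.xi) == 0:
            raise ValueError("umbrella window has no samples")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)


@dataclass
class UmbrellaDataset:
    """Windows along one reaction coordinate at a common temperature."""

    windows: list[UmbrellaWindow]
    temperature: float = 310.0         # K

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset has no windows")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt_kj(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    def wham_windows(self) -> list[UmbrellaWindow]:
        return [w for w in self.windows if not w.one_sided]


@dataclass
class StateDefinition:
    """A named reaction-coordinate interval, e.g. close = (0, 0.4) nm."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("state interval must be non-empty")


@dataclass
class FreeEnergyProfile:
    """G(ξ) at bin centres, min-anchored at zero, with optional bootstrap errors."""

    bin_centers: np.ndarray
    g_kcal: np.ndarray
    g_kt: np.ndarray
    density: np.ndarray                # unbiased p(ξ), normalized over the range
    errors_kcal: Optional[np.ndarray] = None
    replicate_densities: Optional[np.ndarray] = None   # (n_boot, n_bins)
    metadata: dict = field(default_factory=dict)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0]) if len(self.bin_centers) > 1 else 1.0

    def to_tsv(self, path: str) -> None:
        cols = [self.bin_centers, self.g_kcal]
        header = "xi_nm\tG_kcal_per_mol"
        if self.errors_kcal is not None:
            cols.append(self.errors_kcal)
            header += "\terr_kcal_per_mol"
        np.savetxt(path, np.column_stack(cols), header=header, delimiter="\t", comments="")


def _check_overlap(windows: Sequence[UmbrellaWindow]) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        wa, wb = windows[a], windows[b]
        lo = max(wa.xi.min(), wb.xi.min())
        hi = min(wa.xi.max(), wb.xi.max())
        if hi <= lo:
            raise ValueError(
                f"umbrella windows at {wa.center:.3f} and {wb.center:.3f} nm do not "
                "overlap; WHAM cannot connect them"
            )


def _wham_solve(counts: np.ndarray, n_samples: np.ndarray, u_bias_kt: np.ndarray,
                tolerance: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Self-consistent WHAM in log space.

    counts: (n_bins,) pooled histogram counts; n_samples: (n_win,);
    u_bias_kt: (n_win, n_bins) bias energy at bin centres in kT.
    Returns (log p normalized, f_i in kT, iterations, residual).
    """
    n_win = len(n_samples)
    log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
    log_n = np.log(n_samples.astype(float))
    f = np.zeros(n_win)
    resid = np.inf
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [log N_i + f_i - u_ib]
        log_den = logsumexp(log_n[:, None] + f[:, None] - u_bias_kt, axis=0)
        log_p = log_counts - log_den
        log_p -= logsumexp(log_p)
        f_new = -logsumexp(log_p[None, :] - u_bias_kt, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tolerance:
            return log_p, f, it, resid
    warnings.warn(f"WHAM did not converge in {max_iter} iterations "
                  f"(residual {resid:.2e} kT)", stacklevel=3)
    return log_p, f, max_iter, resid


def wham(dataset: UmbrellaDataset, n_bins: int = 100, tolerance: float = 1e-8,
         max_iter: int = 100000, bin_range: Optional[tuple[float, float]] = None
         ) -> FreeEnergyProfile:
    """Unbias the window histograms into a min-anchored free-energy profile."""
    windows = dataset.wham_windows()
    if not windows:
        raise ValueError("no two-sided harmonic windows available for WHAM")
    if len(windows) > 1:
        _check_overlap(windows)
    kbt = dataset.kbt_kj
    all_xi = np.concatenate([w.xi for w in windows])
    if bin_range is None:
        bin_range = (float(all_xi.min()), float(all_xi.max()))
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(n_bins)
    n_samples = np.array([len(w.xi) for w in windows])
    for w in windows:
        h, _ = np.histogram(w.xi, bins=edges)
        counts += h
    u_bias = np.array([0.5 * w.spring_constant * (centers - w.center) ** 2 / kbt
                       for w in windows])
    log_p, f, iterations, resid = _wham_solve(counts, n_samples, u_bias,
                                              tolerance, max_iter)
    occupied = np.isfinite(log_p)
    g_kt = np.full(n_bins, np.nan)
    g_kt[occupied] = -(log_p[occupied] - log_p[occupied].max())
    g_kt -= np.nanmin(g_kt)
    density = np.zeros(n_bins)
    density[occupied] = np.exp(log_p[occupied])
    density /= density.sum() * (edges[1] - edges[0])
    g_kcal = g_kt * kbt * KCAL_PER_KJ
    return FreeEnergyProfile(
        bin_centers=centers,
        g_kcal=g_kcal,
        g_kt=g_kt,
        density=density,
        metadata={
            "n_bins": n_bins, "tolerance_kt": tolerance, "iterations": iterations,
            "residual_kt": resid, "temperature_K": dataset.temperature,
            "bin_range_nm": list(bin_range), "window_offsets_kt": f.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# Autocorrelation-aware bootstrap
# ---------------------------------------------------------------------------

def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """IACT in samples via FFT autocorrelation with Sokal's windowing rule.

    Sums normalized autocorrelations ρ_t until the window exceeds ``c`` times
    the running τ estimate; returns at least 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.std(x) == 0:
        return 1.0
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(xc, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n].real
    rho = acov / acov[0]
    tau = 1.0
    for t in range(1, n):
        tau += 2.0 * rho[t]
        if t >= c * tau:
            break
    return max(tau, 1.0)


def _moving_block_resample(x: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    if block >= n:
        raise ValueError("window shorter than one bootstrap block")
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    out = np.concatenate([x[s:s + block] for s in starts])
    return out[:n]


def bootstrap_error(dataset: UmbrellaDataset, n_bins: int = 100,
                    tolerance: float = 1e-6, max_iter: int = 50000,
                    n_boot: int = 50, seed: int = 0,
                    bin_range: Optional[tuple[float, float]] = None,
                    block_length: Optional[int] = None
                    ) -> tuple[FreeEnergyProfile, np.ndarray]:
    """Per-bin bootstrap standard error of the WHAM profile.

    Each window is resampled with a moving-block bootstrap (block length =
    ceil(IACT), minimum 1) and WHAM is re-solved per replicate; the error is
    the per-bin standard deviation of the min-anchored replicate profiles in
    kcal/mol.  ``block_length`` overrides the IACT-derived choice (1 gives a
    naive i.i.d. bootstrap for comparison).  Returns the full-data profile
    with errors attached, plus the per-window block lengths used.
    """
    windows = dataset.wham_windows()
    rng = np.random.default_rng(seed)
    if n_boot < 2:
        warnings.warn("n_boot < 2 yields degenerate zero errors", stacklevel=2)
    if block_length is not None:
        blocks = np.full(len(windows), int(block_length))
    else:
        blocks = np.array([max(1, int(np.ceil(integrated_autocorrelation_time(w.xi))))
                           for w in windows])
    for w, b in zip(windows, blocks):
        if len(w.xi) < 10 * b:
            raise ValueError(
                f"window at {w.center:.3f} nm has fewer than 10 blocks "
                f"(n={len(w.xi)}, block={b})"
            )
    all_xi = np.concatenate([w.xi for w in windows])
    if bin_range is None:
        bin_range = (float(all_xi.min()), float(all_xi.max()))
    full = wham(dataset, n_bins=n_bins, tolerance=tolerance, max_iter=max_iter,
                bin_range=bin_range)
    reps = np.full((max(n_boot, 1), n_bins), np.nan)
    rep_density = np.zeros((max(n_boot, 1), n_bins))
    for b_idx in range(n_boot):
        new_windows = []
        for w, blk in zip(windows, blocks):
            xi = _moving_block_resample(w.xi, int(blk), rng)
            new_windows.append(UmbrellaWindow(w.center, w.spring_constant, xi))
        rep = wham(UmbrellaDataset(new_windows, dataset.temperature),
                   n_bins=n_bins, tolerance=tolerance, max_iter=max_iter,
                   bin_range=bin_range)
        reps[b_idx] = rep.g_kcal
        rep_density[b_idx] = rep.density
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        errors = np.nanstd(reps, axis=0, ddof=1) if n_boot >= 2 else np.zeros(n_bins)
    full.errors_kcal = errors
    full.replicate_densities = rep_density if n_boot >= 2 else None
    full.metadata["block_lengths"] = blocks.tolist()
    full.metadata["n_boot"] = n_boot
    return full, blocks


def convergence_profile(dataset: UmbrellaDataset, fractions: Sequence[float],
                        n_bins: int = 100, tolerance: float = 1e-6,
                        max_iter: int = 50000) -> dict[float, FreeEnergyProfile]:
    """WHAM re-solved on the leading fraction of every window's series.

    All truncated profiles share the full-data bin grid and are re-anchored at
    the bin where the full-length profile attains its minimum, so they are
    directly comparable.
    """
    windows = dataset.wham_windows()
    all_xi = np.concatenate([w.xi for w in windows])
    bin_range = (float(all_xi.min()), float(all_xi.max()))
    full = wham(dataset, n_bins=n_bins, tolerance=tolerance, max_iter=max_iter,
                bin_range=bin_range)
    anchor = int(np.nanargmin(full.g_kt))
    out: dict[float, FreeEnergyProfile] = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        new_windows = []
        for w in windows:
            n = int(round(frac * len(w.xi)))
            if n == 0:
                raise ValueError(f"fraction {frac} empties window at {w.center:.3f} nm")
            t = None if w.time is None else w.time[:n]
            new_windows.append(UmbrellaWindow(w.center, w.spring_constant, w.xi[:n], t))
        prof = wham(UmbrellaDataset(new_windows, dataset.temperature),
                    n_bins=n_bins, tolerance=tolerance, max_iter=max_iter,
                    bin_range=bin_range)
        if np.isfinite(prof.g_kt[anchor]):
            prof.g_kt = prof.g_kt - prof.g_kt[anchor]
            prof.g_kcal = prof.g_kt * dataset.kbt_kj * KCAL_PER_KJ
        prof.metadata["fraction"] = frac
        out[frac] = prof
    return out


def delta_g(profile: FreeEnergyProfile, state_a: StateDefinition,
            state_b: StateDefinition, temperature: float = 310.0
            ) -> tuple[float, Optional[float]]:
    """ΔG(A→B) = −kT ln(P_B/P_A) in kcal/mol, with bootstrap error when available."""
    kbt_kcal = KB_KJ_PER_MOL_K * temperature * KCAL_PER_KJ

    def _dg(density: np.ndarray) -> float:
        xi = profile.bin_centers
        pa = density[(xi >= state_a.lo) & (xi < state_a.hi)].sum()
        pb = density[(xi >= state_b.lo) & (xi < state_b.hi)].sum()
        if pa <= 0 or pb <= 0:
            raise ValueError(
                f"state {state_a.name if pa <= 0 else state_b.name!r} has zero "
                "integrated density within the profile"
            )
        return -kbt_kcal * np.log(pb / pa)

    value = _dg(profile.density)
    err = None
    if profile.replicate_densities is not None:
        vals = []
        for dens in profile.replicate_densities:
            try:
                vals.append(_dg(dens))
            except ValueError:
                continue
        if len(vals) >= 2:
            err = float(np.std(vals, ddof=1))
    return float(value), err


# ---------------------------------------------------------------------------
# Plain-text I/O: per-window two-column series plus a metadata table
# ---------------------------------------------------------------------------

def write_umbrella_dataset(dataset: UmbrellaDataset, directory: str,
                           prefix: str = "window") -> str:
    """Write per-window ``time xi`` text files plus a window metadata table.

    Returns the metadata path.  Layout matches common umbrella
    post-processors: one whitespace-delimited two-column file per window.
    """
    os.makedirs(directory, exist_ok=True)
    meta_path = os.path.join(directory, f"{prefix}_meta.tsv")
    with open(meta_path, "w") as meta:
        meta.write("file\tcenter_nm\tspring_kj_mol_nm2\ttemperature_K\n")
        for i, w in enumerate(dataset.windows):
            fname = f"{prefix}_{i:03d}.dat"
            t = w.time if w.time is not None else np.arange(len(w.xi), dtype=float)
            np.savetxt(os.path.join(directory, fname), np.column_stack([t, w.xi]),
                       fmt="%.6f")
            meta.write(f"{fname}\t{w.center:.6f}\t{w.spring_constant:.6f}"
                       f"\t{dataset.temperature:.2f}\n")
    return meta_path


def load_umbrella_dataset(meta_path: str) -> UmbrellaDataset:
    """Read a dataset written by :func:`write_umbrella_dataset`."""
    directory = os.path.dirname(os.path.abspath(meta_path))
    windows = []
    temperature = 310.0
    with open(meta_path) as fh:
        header = fh.readline()
        if not header.startswith("file"):
            raise ValueError("unrecognized umbrella metadata header")
        for line in fh:
            if not line.strip():
                continue
            fname, center, k, temp = line.split()
            data = np.loadtxt(os.path.join(directory, fname))
            data = np.atleast_2d(data)
            windows.append(UmbrellaWindow(float(center), float(k),
                                          data[:, 1], data[:, 0]))
            temperature = float(temp)
    return UmbrellaDataset(windows, temperature)
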