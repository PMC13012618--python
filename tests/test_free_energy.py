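"""WHAM reconstruction, autocorrelation-aware bootstrap, state free energies."""

import numpy as np
import pytest

from allonet import free_energy as fe
from allonet import synthetic
from allonet.free_energy import (FreeEnergyProfile, KB_KJ_PER_MOL_K,
                                 KCAL_PER_KJ, StateDefinition, UmbrellaDataset,
                                 UmbrellaWindow, bootstrap_error,
                                 convergence_profile, delta_g,
                                 integrated_autocorrelation_time,
                                 load_umbrella_dataset, wham,
                                 write_umbrella_dataset)

KBT = KB_KJ_PER_MOL_K * 310.0


def _harmonic_dataset(n=2000, seed=0):
    spec = synthetic.UmbrellaSpec(n_samples=n, seed=seed)
    return synthetic.make_umbrella_dataset(spec)


class TestWham:
    def test_single_window_negligible_bias_reduces_to_log_histogram(self):
        rng = np.random.default_rng(0)
        xi = rng.normal(0.6, 0.05, 5000)
        ds = UmbrellaDataset([UmbrellaWindow(0.6, 1e-9, xi)], 310.0)
        prof = wham(ds, n_bins=25)
        h, edges = np.histogram(xi, bins=25, range=(xi.min(), xi.max()))
        expected = -np.log(h / h.max())
        occupied = h > 0
        assert np.abs(prof.g_kt[occupied] - expected[occupied]).max() < 1e-6

    def test_harmonic_recovery_small(self):
        ds, truth = _harmonic_dataset(n=2000, seed=1)
        prof = wham(ds, n_bins=80)
        grid, g_true = truth.analytic_pmf
        interp = np.interp(prof.bin_centers, grid, g_true)
        mask = (prof.bin_centers > 0.35) & (prof.bin_centers < 1.15)
        diff = prof.g_kt[mask] - interp[mask]
        diff -= diff.mean()
        assert np.sqrt((diff ** 2).mean()) < 0.2

    def test_non_overlapping_windows_rejected(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.3, 1500.0, rng.normal(0.3, 0.01, 500))
        w2 = UmbrellaWindow(1.2, 1500.0, rng.normal(1.2, 0.01, 500))
        with pytest.raises(ValueError, match="overlap"):
            wham(UmbrellaDataset([w1, w2], 310.0))

    def test_bin_doubling_stable(self):
        ds, truth = _harmonic_dataset(n=5000, seed=2)
        p1 = wham(ds, n_bins=50)
        p2 = wham(ds, n_bins=100)
        interp = np.interp(p1.bin_centers, p2.bin_centers, p2.g_kt)
        mask = (p1.bin_centers > 0.4) & (p1.bin_centers < 1.1)
        diff = p1.g_kt[mask] - interp[mask]
        assert np.abs(diff - diff.mean()).max() < 0.2

    def test_min_anchored_and_density_normalized(self):
        ds, _ = _harmonic_dataset(n=1000, seed=3)
        prof = wham(ds, n_bins=60)
        assert np.nanmin(prof.g_kt) == 0.0
        assert (prof.density * prof.bin_width).sum() == pytest.approx(1.0)

    def test_one_sided_windows_excluded(self):
        ds, _ = _harmonic_dataset(n=500, seed=4)
        ds.windows[0].one_sided = True
        prof = wham(ds, n_bins=40)
        assert len(prof.metadata["window_offsets_kt"]) == len(ds.windows) - 1


class TestIact:
    def test_ar1_iact_close_to_theory(self):
        phi = 0.9
        rng = np.random.default_rng(5)
        x = np.zeros(200000)
        eps = rng.normal(size=len(x))
        for t in range(1, len(x)):
            x[t] = phi * x[t - 1] + eps[t]
        tau = integrated_autocorrelation_time(x)
        expected = (1 + phi) / (1 - phi)
        assert abs(tau - expected) / expected < 0.3

    def test_iid_iact_near_one(self):
        x = np.random.default_rng(6).normal(size=50000)
        assert integrated_autocorrelation_time(x) < 1.5


def _ar1_dataset(phi, n=2000, seed=0):
    """Umbrella ladder whose window series are AR(1) with the right stationary law."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(0.3, 1.2, 10)
    k = 1500.0
    sd = np.sqrt(KBT / k)
    windows = []
    for c in centers:
        innov = rng.normal(0, sd * np.sqrt(1 - phi ** 2), n)
        x = np.empty(n)
        x[0] = rng.normal(0, sd)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
        windows.append(UmbrellaWindow(c, k, c + x))
    return UmbrellaDataset(list(windows), 310.0)


class TestBootstrap:
    def test_ar1_blocks_exceed_five_and_inflate_errors(self):
        ds = _ar1_dataset(0.9, seed=1)
        prof, blocks = bootstrap_error(ds, n_bins=40, n_boot=25, seed=2,
                                       tolerance=1e-5)
        assert blocks.min() > 5
        naive, _ = bootstrap_error(_ar1_dataset(0.9, seed=1), n_bins=40,
                                   n_boot=25, seed=2, tolerance=1e-5,
                                   block_length=1)
        mask = np.isfinite(prof.errors_kcal) & np.isfinite(naive.errors_kcal)
        assert prof.errors_kcal[mask].mean() > 1.5 * naive.errors_kcal[mask].mean()

    def test_iid_reduces_to_naive(self):
        ds = _ar1_dataset(0.0, seed=3)
        prof, blocks = bootstrap_error(ds, n_bins=40, n_boot=80, seed=4,
                                       tolerance=1e-5)
        assert np.all(blocks <= 2)
        naive, _ = bootstrap_error(_ar1_dataset(0.0, seed=3), n_bins=40,
                                   n_boot=80, seed=4, tolerance=1e-5,
                                   block_length=1)
        mask = np.isfinite(prof.errors_kcal) & np.isfinite(naive.errors_kcal)
        ratio = prof.errors_kcal[mask].mean() / naive.errors_kcal[mask].mean()
        assert 0.8 < ratio < 1.2

    def test_single_replicate_degenerate(self):
        ds = _ar1_dataset(0.0, n=500, seed=5)
        with pytest.warns(UserWarning, match="degenerate"):
            prof, _ = bootstrap_error(ds, n_bins=30, n_boot=1, seed=0,
                                      tolerance=1e-4)
        assert np.all(prof.errors_kcal == 0.0)

    def test_window_shorter_than_blocks_rejected(self):
        rng = np.random.default_rng(7)
        phi = 0.995
        n = 200
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal(0, 0.01)
        ds = UmbrellaDataset([UmbrellaWindow(0.5, 1500.0, 0.5 + x)], 310.0)
        with pytest.raises(ValueError, match="blocks"):
            bootstrap_error(ds, n_bins=20, n_boot=5, seed=0)


class TestConvergence:
    def test_full_fraction_identical(self):
        ds, _ = _harmonic_dataset(n=1000, seed=6)
        full = wham(ds, n_bins=50, tolerance=1e-10)
        prof = convergence_profile(ds, [1.0], n_bins=50, tolerance=1e-10)[1.0]
        anchored = full.g_kt - full.g_kt[int(np.nanargmin(full.g_kt))]
        assert np.allclose(prof.g_kt, anchored, atol=1e-7, equal_nan=True)

    def test_half_fraction_close_on_harmonic_data(self):
        ds, _ = _harmonic_dataset(n=4000, seed=7)
        profs = convergence_profile(ds, [0.5, 1.0], n_bins=60)
        mask = ((profs[1.0].bin_centers > 0.4) & (profs[1.0].bin_centers < 1.1)
                & np.isfinite(profs[0.5].g_kt) & np.isfinite(profs[1.0].g_kt))
        assert np.abs(profs[0.5].g_kt[mask] - profs[1.0].g_kt[mask]).max() < 0.3

    def test_fraction_ordering_recorded(self):
        ds, _ = _harmonic_dataset(n=500, seed=8)
        profs = convergence_profile(ds, [0.25, 0.5, 1.0], n_bins=30)
        assert [profs[f].metadata["fraction"] for f in (0.25, 0.5, 1.0)] \
            == [0.25, 0.5, 1.0]

    def test_bad_fraction_rejected(self):
        ds, _ = _harmonic_dataset(n=500, seed=9)
        with pytest.raises(ValueError):
            convergence_profile(ds, [0.0])


class TestDeltaG:
    def _flat_profile(self):
        centers = np.linspace(0.0, 1.0, 50)
        density = np.full(50, 1.0 / (centers[1] - centers[0]) / 50)
        g = np.zeros(50)
        return FreeEnergyProfile(centers, g, g, density)

    def test_flat_profile_equal_states_zero(self):
        prof = self._flat_profile()
        # intervals covering equally many bin centres of the uniform density
        a = StateDefinition("a", -0.01, 0.4)
        b = StateDefinition("b", 0.6, 1.01)
        dg, _ = delta_g(prof, a, b)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry(self):
        ds, _ = _harmonic_dataset(n=2000, seed=10)
        prof = wham(ds, n_bins=60)
        a = StateDefinition("close", 0.0, 0.4)
        b = StateDefinition("far", 0.65, 10.0)
        ab, _ = delta_g(prof, a, b)
        ba, _ = delta_g(prof, b, a)
        assert ab == pytest.approx(-ba)

    def test_two_gaussian_weight_ratio(self):
        centers = np.linspace(-1.0, 1.0, 400)
        w = centers[1] - centers[0]
        density = (10 * np.exp(-0.5 * ((centers + 0.5) / 0.05) ** 2)
                   + 1 * np.exp(-0.5 * ((centers - 0.5) / 0.05) ** 2))
        density /= density.sum() * w
        g = np.zeros_like(centers)
        prof = FreeEnergyProfile(centers, g, g, density)
        a = StateDefinition("a", -1.0, 0.0)
        b = StateDefinition("b", 0.0, 1.0)
        dg, _ = delta_g(prof, a, b)
        expected = -KBT * KCAL_PER_KJ * np.log(1 / 10)
        assert dg == pytest.approx(expected, rel=1e-3)

    def test_invariant_under_profile_shift(self):
        ds, _ = _harmonic_dataset(n=2000, seed=11)
        prof = wham(ds, n_bins=60)
        shifted = FreeEnergyProfile(prof.bin_centers, prof.g_kcal + 3.0,
                                    prof.g_kt + 3.0 / (KBT * KCAL_PER_KJ),
                                    prof.density)
        a = StateDefinition("close", 0.0, 0.4)
        b = StateDefinition("far", 0.65, 10.0)
        assert delta_g(prof, a, b)[0] == pytest.approx(delta_g(shifted, a, b)[0])

    def test_empty_state_rejected(self):
        prof = self._flat_profile()
        with pytest.raises(ValueError, match="zero"):
            delta_g(prof, StateDefinition("a", 5.0, 6.0),
                    StateDefinition("b", 0.0, 0.5))


class TestIO:
    def test_roundtrip(self, tmp_path):
        ds, _ = _harmonic_dataset(n=300, seed=12)
        meta = write_umbrella_dataset(ds, str(tmp_path))
        back = load_umbrella_dataset(meta)
        assert len(back.windows) == len(ds.windows)
        assert back.temperature == ds.temperature
        for a, b in zip(ds.windows, back.windows):
            assert a.center == pytest.approx(b.center)
            assert a.spring_constant == pytest.approx(b.spring_constant)
            assert np.abs(a.xi - b.xi).max() < 1e-6
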