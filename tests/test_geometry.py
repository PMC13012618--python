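"""Order parameters, beta-content, PCA and statistics helpers."""

import numpy as np
import pytest

from allonet import geometry, synthetic
from allonet.geometry import (BetaContentParams, OrderParameterSeries,
                              beta_content, correlate, dihedral,
                              dihedral_from_points, group_distance, histogram,
                              pca, subdomain_torsion, switching_function)
from allonet.model import AtomSelection, FrameEnsemble, Topology, select
from conftest import dihedral_oracle


class TestDihedral:
    def test_matches_independent_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pts = rng.normal(0, 1, (4, 3))
            got = dihedral_from_points(*pts)[0]
            assert abs(got - dihedral_oracle(*pts)) < 1e-9

    def test_mirror_reflection_flips_sign(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        a = dihedral_from_points(*pts)[0]
        b = dihedral_from_points(*mirrored)[0]
        assert abs(a + b) < 1e-9 or abs(abs(a) - 180.0) < 1e-9

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            dihedral_from_points(*pts)

    def test_requires_distinct_atoms(self):
        top = Topology.from_atom_records(["C"] * 4, [1, 2, 3, 4], ["UNK"] * 4)
        ens = FrameEnsemble(top, np.random.default_rng(0).normal(size=(1, 4, 3)))
        with pytest.raises(ValueError, match="distinct"):
            dihedral(ens, [0, 1, 2, 2])


class TestSubdomainTorsion:
    def test_fixture_angle(self):
        top, ens = synthetic.make_geometry_fixture("lobe_torsion", 35.0)
        groups = [select(top, f"resid {r}") for r in (1, 2, 3, 4)]
        assert abs(subdomain_torsion(ens, groups).values[0] - 35.0) < 1e-6

    def test_planar_trans_is_180(self):
        top, ens = synthetic.make_geometry_fixture("lobe_torsion", 180.0)
        groups = [select(top, f"resid {r}") for r in (1, 2, 3, 4)]
        assert abs(abs(subdomain_torsion(ens, groups).values[0]) - 180.0) < 1e-6

    def test_matches_independent_com_dihedral_oracle(self):
        top, ens0 = synthetic.make_geometry_fixture("lobe_torsion", 60.0)
        rng = np.random.default_rng(3)
        coords = ens0.coords[0][None] + rng.normal(0, 0.05, (20, top.n_atoms, 3))
        ens = FrameEnsemble(top, coords)
        groups = [select(top, f"resid {r}") for r in (1, 2, 3, 4)]
        series = subdomain_torsion(ens, groups)
        for f in range(20):
            coms = [coords[f][g.indices].mean(axis=0) for g in groups]
            assert abs(series.values[f] - dihedral_oracle(*coms)) < 1e-9


class TestGroupDistance:
    def _two_atoms(self, d):
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        coords = np.array([[[0, 0, 0], [d, 0, 0]]], dtype=float)
        return top, FrameEnsemble(top, coords)

    def test_two_single_atoms_both_modes(self):
        top, ens = self._two_atoms(0.35)
        a, b = select(top, "resid 1"), select(top, "resid 2")
        assert abs(group_distance(ens, a, b, "com").values[0] - 0.35) < 1e-12
        assert abs(group_distance(ens, a, b, "min").values[0] - 0.35) < 1e-12

    def test_min_matches_brute_force(self, planted_small):
        top, ens, _ = planted_small
        short = ens.subset_frames(slice(0, 10))
        a = select(top, "resid 1-5")
        b = select(top, "resid 20-25")
        series = group_distance(short, a, b, "min")
        for f in range(10):
            brute = min(np.linalg.norm(short.coords[f][i] - short.coords[f][j])
                        for i in a.indices for j in b.indices)
            assert abs(series.values[f] - brute) < 1e-12

    def test_self_distance_zero(self, planted_small):
        top, ens, _ = planted_small
        a = select(top, "resid 3-7")
        assert group_distance(ens.subset_frames(slice(0, 3)), a, a, "com").values.max() < 1e-12


class TestBetaContent:
    PARAMS = BetaContentParams(segment_a=[1, 2, 3], segment_b=[4, 5, 6])

    def test_hairpin_scores_eligible_block_count(self):
        _, ens = synthetic.make_geometry_fixture("ideal_hairpin")
        s = beta_content(ens, self.PARAMS).values[0]
        assert abs(s - 1.0) < 1e-3

    def test_coil_scores_near_zero(self):
        _, ens = synthetic.make_geometry_fixture("coil")
        assert beta_content(ens, self.PARAMS).values[0] < 0.1

    def test_switching_limit_at_r0(self):
        p = self.PARAMS
        assert switching_function(p.r0_nm, p.r0_nm, p.n_exp, p.m_exp) == pytest.approx(8 / 12)

    def test_rotation_translation_invariant(self):
        from scipy.spatial.transform import Rotation
        top, ens = synthetic.make_geometry_fixture("ideal_hairpin")
        R = Rotation.random(random_state=9).as_matrix()
        moved = FrameEnsemble(top, (ens.coords[0] @ R.T + 2.5)[None])
        s0 = beta_content(ens, self.PARAMS).values[0]
        s1 = beta_content(moved, self.PARAMS).values[0]
        assert abs(s0 - s1) < 1e-9

    def test_short_segment_rejected(self):
        _, ens = synthetic.make_geometry_fixture("ideal_hairpin")
        with pytest.raises(ValueError, match="at least 3"):
            beta_content(ens, BetaContentParams(segment_a=[1, 2], segment_b=[4, 5, 6]))


class TestPCA:
    def _orthogonal_data(self, variances, n_frames=120, seed=0):
        """Data whose sample covariance is exactly diag(variances)."""
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(n_frames, len(variances))))
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)  # re-orthonormalize after centering
        return q * np.sqrt((n_frames - 1) * np.asarray(variances))

    def test_diagonal_covariance_fractions(self):
        variances = np.array([9, 1, 1, 1, 1, 1]) * 1e-4
        flat = self._orthogonal_data(variances)
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        ens = FrameEnsemble(top, flat.reshape(-1, 2, 3))
        res = pca(ens, select(top, "all"), n_components=2)
        assert abs(res.variance_fractions[0] - 9 / 14) < 1e-9
        assert abs(res.variance_fractions.sum() - 1.0) < 1e-9

    def test_duplication_invariance(self, planted_small):
        top, ens, _ = planted_small
        short = ens.subset_frames(slice(0, 200))
        doubled = short.concat(short)
        sel = select(top, "all")
        a = pca(short, sel)
        b = pca(doubled, sel)
        assert np.allclose(a.variance_fractions, b.variance_fractions, atol=1e-9)

    def test_projections_zero_mean_variance_eigenvalues(self, planted_small):
        top, ens, _ = planted_small
        res = pca(ens.subset_frames(slice(0, 500)), select(top, "all"), n_components=3)
        proj = res.projections
        assert np.abs(proj.mean(axis=0)).max() < 1e-9
        assert np.allclose(proj.var(axis=0, ddof=1), res.eigenvalues[:3], rtol=1e-9)

    def test_atom_permutation_invariance(self):
        variances = np.array([4, 2, 1, 1, 1, 1]) * 1e-4
        flat = self._orthogonal_data(variances, seed=3)
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        ens = FrameEnsemble(top, flat.reshape(-1, 2, 3))
        perm = flat.reshape(-1, 2, 3)[:, ::-1, :]
        ens_p = FrameEnsemble(top, perm)
        sel = select(top, "all")
        assert np.allclose(pca(ens, sel).variance_fractions,
                           pca(ens_p, sel).variance_fractions, atol=1e-12)

    def test_too_few_frames(self, planted_small):
        top, ens, _ = planted_small
        with pytest.raises(ValueError):
            pca(ens.subset_frames(slice(0, 1)), select(top, "all"))


class TestStatistics:
    def test_affine_relation_r2_one(self):
        a = OrderParameterSeries("a", np.arange(50.0), "nm")
        b = OrderParameterSeries("b", 2 * np.arange(50.0) + 1, "nm")
        assert correlate(a, b) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        a = OrderParameterSeries("a", rng.normal(size=10000), "nm")
        b = OrderParameterSeries("b", rng.normal(size=10000), "nm")
        assert correlate(a, b) < 0.01

    def test_matches_covariance_ratio_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        r2 = correlate(OrderParameterSeries("x", x, "nm"),
                       OrderParameterSeries("y", y, "nm"))
        oracle = (np.cov(x, y)[0, 1] ** 2) / (np.var(x, ddof=1) * np.var(y, ddof=1))
        assert abs(r2 - oracle) < 1e-12

    def test_zero_variance_error(self):
        a = OrderParameterSeries("a", np.ones(10), "nm")
        b = OrderParameterSeries("b", np.arange(10.0), "nm")
        with pytest.raises(ValueError, match="zero-variance"):
            correlate(a, b)

    def test_histogram_constant_series(self):
        s = OrderParameterSeries("s", np.full(100, 2.0), "nm")
        edges, density = histogram(s, bins=np.array([1.5, 2.5]))
        assert density[0] == pytest.approx(1.0 / 1.0)

    def test_histogram_normalized(self):
        rng = np.random.default_rng(1)
        s = OrderParameterSeries("s", rng.uniform(0, 5, 100000), "nm")
        edges, density = histogram(s, bins=np.linspace(0, 5, 11))
        widths = np.diff(edges)
        assert abs((density * widths).sum() - 1.0) < 1e-12
        assert np.abs(density - 0.2).max() < 0.2 * 0.05

    def test_histogram_empty_series(self):
        with pytest.raises(ValueError):
            histogram(OrderParameterSeries("s", np.array([]), "nm"), bins=5)
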