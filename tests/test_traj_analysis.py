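import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stepfold import traj_analysis as TA
from stepfold.dmd_engine import Trajectory


def make_traj(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Trajectory(times=np.arange(n, dtype=float), coords=coords,
                      potential_energies=np.zeros(n),
                      kinetic_energies=np.zeros(n), temperature=0.3)


def random_points(n, seed):
    return np.random.default_rng(seed).normal(scale=3.0, size=(n, 3))


class TestSuperpose:
    def test_identity(self):
        X = random_points(6, 0)
        _, _, rmsd = TA.superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self):
        X = random_points(8, 1)
        rot = Rotation.from_euler("zyx", [35, -60, 110], degrees=True)
        Y = X @ rot.as_matrix().T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = TA.superpose(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-9)

    def test_mirror_not_allowed(self):
        """Kabsch must return a proper rotation even for a reflected set."""
        X = random_points(5, 2)
        Y = X.copy()
        Y[:, 2] *= -1
        R, _, _ = TA.superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_rotation_grid_brute_force(self):
        X = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 1.5, 0], [0.4, 0.4, 1.1]])
        Y = np.array([[0.1, 0, 0], [1.8, 0.4, 0], [-0.2, 1.6, 0.2],
                      [0.5, 0.2, 1.0]])
        _, _, rmsd = TA.superpose(X, Y)
        # dense Euler-angle grid oracle
        step = 6.0
        angles = np.arange(0.0, 360.0, step)
        half = np.arange(-90.0, 90.1, step)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        best = np.inf
        for a in angles:
            for b in half:
                for c in angles:
                    M = Rotation.from_euler("zyz", [a, b, c],
                                            degrees=True).as_matrix()
                    d = Xc @ M.T - Yc
                    best = min(best, np.sqrt(np.mean(np.sum(d * d, axis=1))))
        assert rmsd <= best + 1e-9
        assert best - rmsd < 0.05  # grid resolution

    def test_agreement_with_scipy(self):
        X = random_points(10, 3)
        Y = random_points(10, 4)
        R, t, rmsd = TA.superpose(X, Y)
        est, ssd = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
        fitted = (X - X.mean(0)) @ est.as_matrix().T
        scipy_rmsd = np.sqrt(np.mean(np.sum((fitted - (Y - Y.mean(0))) ** 2,
                                            axis=1)))
        assert rmsd == pytest.approx(scipy_rmsd, abs=1e-9)

    def test_symmetry(self):
        X = random_points(7, 5)
        Y = random_points(7, 6)
        _, _, ab = TA.superpose(X, Y)
        _, _, ba = TA.superpose(Y, X)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            TA.superpose(random_points(4, 0), random_points(5, 0))
        with pytest.raises(ValueError):
            TA.superpose(random_points(2, 0), random_points(2, 0))


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = random_points(5, 7)
        traj = make_traj(np.repeat(base[None], 10, axis=0))
        np.testing.assert_allclose(TA.rmsf(traj), 0.0, atol=1e-12)

    def test_isotropic_jitter_moment(self):
        rng = np.random.default_rng(8)
        base = random_points(6, 9) * 4
        sigma = 0.3
        coords = base[None] + rng.normal(scale=sigma, size=(10_000, 6, 3))
        vals = TA.rmsf(make_traj(coords), fit=False)
        np.testing.assert_allclose(vals, sigma * np.sqrt(3), rtol=0.05)

    def test_rigid_translation_removed_by_fit(self):
        base = random_points(5, 10)
        shifts = np.linspace(0, 9, 10)[:, None] * np.array([1.0, 0.5, -0.2])
        coords = base[None] + shifts[:, None, :]
        np.testing.assert_allclose(TA.rmsf(make_traj(coords), fit=True),
                                   0.0, atol=1e-9)

    def test_single_frame_warns_zero(self):
        traj = make_traj(random_points(4, 11)[None])
        with pytest.warns(UserWarning):
            vals = TA.rmsf(traj)
        np.testing.assert_array_equal(vals, 0.0)


class TestCorrelationMap:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(12)
        coords = random_points(6, 13)[None] + rng.normal(
            scale=0.5, size=(200, 6, 3))
        cmap = TA.correlation_map(make_traj(coords), fit=False)
        np.testing.assert_allclose(np.diag(cmap.matrix), 1.0, atol=1e-12)
        np.testing.assert_allclose(cmap.matrix, cmap.matrix.T, atol=1e-12)

    def test_identical_motion_fully_correlated(self):
        rng = np.random.default_rng(14)
        disp = rng.normal(size=(300, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.repeat(disp, 2, axis=1)
        cmap = TA.correlation_map(make_traj(coords), fit=False)
        assert cmap.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_opposite_motion_anticorrelated(self):
        rng = np.random.default_rng(15)
        disp = rng.normal(size=(300, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = np.stack([base[0] + disp, base[1] - disp], axis=1)
        cmap = TA.correlation_map(make_traj(coords), fit=False)
        assert cmap.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_residue_flagged(self):
        rng = np.random.default_rng(16)
        coords = np.zeros((100, 3, 3))
        coords[:, 0] = rng.normal(size=(100, 3))
        coords[:, 1] = np.array([5.0, 0, 0])       # frozen
        coords[:, 2] = np.array([0, 5.0, 0]) + rng.normal(size=(100, 3))
        cmap = TA.correlation_map(make_traj(coords), fit=False)
        assert cmap.flagged == [1]
        assert cmap.matrix[1, 1] == 1.0
        assert np.all(cmap.matrix[1, [0, 2]] == 0.0)

    def test_invariant_to_global_rigid_motion(self):
        rng = np.random.default_rng(17)
        base = random_points(5, 18) * 3
        coords = base[None] + rng.normal(scale=0.4, size=(400, 5, 3))
        moved = np.empty_like(coords)
        for f in range(len(coords)):
            rot = Rotation.from_euler("z", 0.25 * f, degrees=True).as_matrix()
            moved[f] = coords[f] @ rot.T + np.array([0.01 * f, 0.0, -0.02 * f])
        m1 = TA.correlation_map(make_traj(coords), fit=True).matrix
        m2 = TA.correlation_map(make_traj(moved), fit=True).matrix
        np.testing.assert_allclose(m1, m2, atol=1e-6)


class TestDifferenceMap:
    def _map(self, matrix, labels=None):
        n = len(matrix)
        return TA.CorrelationMap(labels=labels or [f"A{i}" for i in range(n)],
                                 matrix=np.asarray(matrix, dtype=float))

    def test_self_difference_zero(self):
        rng = np.random.default_rng(19)
        m = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (4, 4))),
                    -1, 1)
        np.fill_diagonal(m, 1.0)
        cmap = self._map(m)
        np.testing.assert_array_equal(TA.difference_map(cmap, cmap), 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(20)

        def sym(a):
            m = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(m, 1.0)
            return m
        A = self._map(sym(rng.uniform(-1, 1, (5, 5))))
        B = self._map(sym(rng.uniform(-1, 1, (5, 5))))
        np.testing.assert_allclose(TA.difference_map(A, B),
                                   -TA.difference_map(B, A), atol=1e-12)

    def test_label_mismatch_reported(self):
        A = self._map(np.eye(3))
        B = self._map(np.eye(3), labels=["A0", "A1", "B9"])
        with pytest.raises(ValueError, match="B9"):
            TA.difference_map(A, B)

    def test_decoupled_block_shows_negative(self):
        """Two residues moving together in A but independently in B leave a
        negative off-diagonal block in A-to-B difference reversed."""
        rng = np.random.default_rng(21)
        shared = rng.normal(size=(500, 1, 3))
        base = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 8.0, 0]])
        coupled = base[None] + np.concatenate(
            [shared, shared, rng.normal(size=(500, 1, 3))], axis=1)
        indep = base[None] + rng.normal(size=(500, 3, 3))
        A = TA.correlation_map(make_traj(coupled), fit=False)
        B = TA.correlation_map(make_traj(indep), fit=False)
        D = TA.difference_map(B, A)
        assert D[0, 1] < -0.8  # coupling lost
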