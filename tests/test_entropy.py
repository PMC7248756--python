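import numpy as np
import pytest
from scipy import constants
from scipy.spatial.transform import Rotation

from oligorot import (
    CovarianceModel,
    SyntheticSpec,
    RotationCourse,
    Trajectory,
    covariance,
    entropy_difference,
    generate_gaussian_trajectory,
    generate_hexamer_trajectory,
    pca_modes,
    project_trajectory,
    quasiharmonic_entropy,
    schlitter_entropy,
    select_atoms,
)

from conftest import build_trajectory, small_hexamer_spec, small_topology

R = constants.R
AMU_A2 = constants.atomic_mass * 1e-20
KT300 = constants.k * 300.0


def model_from_eigenvalues(lam_mass_weighted_A2, mass=12.0):
    """Diagonal mass-weighted CovarianceModel with given spectrum (amu·Å²)."""
    lam = np.asarray(lam_mass_weighted_A2, dtype=float)
    n_atoms = int(np.ceil(len(lam) / 3))
    full = np.zeros(3 * n_atoms)
    full[:len(lam)] = lam
    return CovarianceModel(matrix=np.diag(full), masses=np.full(n_atoms, mass),
                           mass_weighted=True, n_frames=1000)


class TestCovariance:
    def test_static_trajectory_zero_matrix(self, eclipsed_traj):
        traj, _ = eclipsed_traj
        idx = select_atoms(traj, chains="A", atom_names="CA")
        cov = covariance(traj, idx, window=(0.0, 4.0), fit=False)
        assert np.abs(cov.matrix).max() < 1e-18

    def test_diagonal_gaussian_within_sampling_tolerance(self):
        rng = np.random.default_rng(0)
        n_atoms, n_frames = 4, 20000
        variances = rng.uniform(0.2, 2.0, 3 * n_atoms)
        rows = [("A", i + 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)) for i in range(n_atoms)]
        coords = (rng.normal(size=(n_frames, 3 * n_atoms)) * np.sqrt(variances)
                  ).reshape(n_frames, n_atoms, 3)
        traj = build_trajectory(rows, coords)
        cov = covariance(traj, np.arange(n_atoms), window=(0.0, n_frames - 1.0),
                         mass_weighted=False, fit=False)
        diag = np.diag(cov.matrix)
        tol = 3.0 * variances * np.sqrt(2.0 / n_frames)
        assert np.all(np.abs(diag - variances) < tol)

    def test_tumbling_rigid_body_fit_removes_everything(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(12, 3)) * 6
        rows = [("A", i + 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)) for i in range(12)]
        coords = np.array([
            base @ Rotation.random(random_state=i).as_matrix().T
            + rng.normal(size=3) * 15
            for i in range(200)])
        traj = build_trajectory(rows, coords)
        cov = covariance(traj, np.arange(12), window=(0.0, 199.0), fit=True)
        assert cov.eigenvalues().max() < 1e-6

    def test_mass_weighting_scales_matrix(self):
        rng = np.random.default_rng(2)
        rows = [("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
                ("A", 1, "GLY", "O", "O", (4.0, 0.0, 0.0)),
                ("A", 1, "GLY", "CA", "C", (0.0, 4.0, 0.0))]
        coords = np.array([[(0, 0, 0), (4, 0, 0), (0, 4, 0)]] * 50, dtype=float)
        coords += rng.normal(0, 0.3, coords.shape)
        traj = build_trajectory(rows, coords)
        plain = covariance(traj, np.arange(3), window=(0.0, 49.0),
                           mass_weighted=False, fit=False)
        weighted = covariance(traj, np.arange(3), window=(0.0, 49.0),
                              mass_weighted=True, fit=False)
        w = np.sqrt(np.repeat(traj.table.masses, 3))
        np.testing.assert_allclose(weighted.matrix, plain.matrix * np.outer(w, w),
                                   rtol=1e-10)

    def test_rank_deficiency_warning(self, eclipsed_traj):
        traj, _ = eclipsed_traj
        idx = select_atoms(traj, chains="A")
        with pytest.warns(UserWarning, match="rank-deficient"):
            covariance(traj, idx, window=(0.0, 4.0))


class TestSchlitter:
    def test_zero_covariance(self):
        model = model_from_eigenvalues([0.0, 0.0, 0.0])
        assert schlitter_entropy(model, dropped_modes=0).value == 0.0

    def test_single_mode_closed_form(self):
        # variance chosen so (kT e^2/hbar^2) * lambda = e^2 - 1  =>  S = R
        lam_si = (np.e ** 2 - 1) * constants.hbar ** 2 / (KT300 * np.e ** 2)
        model = model_from_eigenvalues([lam_si / AMU_A2])
        s = schlitter_entropy(model, dropped_modes=2)
        assert s.value == pytest.approx(R, rel=1e-12)

    def test_spectrum_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        lam = rng.uniform(0.001, 0.5, 9)  # amu·Å², 3-atom fixture
        model = model_from_eigenvalues(lam, mass=14.0)
        s = schlitter_entropy(model, dropped_modes=0)
        # independent brute-force evaluation of the formula
        expected = 0.5 * R * np.sum(np.log1p(
            KT300 * np.e ** 2 / constants.hbar ** 2 * np.sort(lam) * AMU_A2))
        assert s.value == pytest.approx(expected, rel=1e-12)

    def test_requires_mass_weighting(self):
        model = model_from_eigenvalues([0.1])
        model.mass_weighted = False
        with pytest.raises(ValueError):
            schlitter_entropy(model)


class TestQuasiharmonic:
    def test_stiff_mode_contribution_vanishes(self):
        tiny = model_from_eigenvalues([1e-12])
        s = quasiharmonic_entropy(tiny, dropped_modes=2)
        assert 0 <= s.value < 1e-6

    def test_alpha_one_closed_form(self):
        lam_si = constants.hbar ** 2 / KT300   # alpha = 1
        model = model_from_eigenvalues([lam_si / AMU_A2])
        s = quasiharmonic_entropy(model, dropped_modes=2)
        expected = R * (1.0 / (np.e - 1.0) - np.log(1.0 - np.exp(-1.0)))
        assert s.value == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.6525, abs=1e-3)

    def test_zero_retained_eigenvalue_errors(self):
        model = model_from_eigenvalues([0.0, 0.1, 0.1])
        with pytest.raises(ValueError):
            quasiharmonic_entropy(model, dropped_modes=0)

    def test_schlitter_upper_bound(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            lam = np.random.default_rng(seed).uniform(1e-4, 2.0, 12)
            model = model_from_eigenvalues(lam)
            s = schlitter_entropy(model, dropped_modes=0)
            q = quasiharmonic_entropy(model, dropped_modes=0)
            assert s.value >= q.value

    def test_orthogonal_basis_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(9, 9))
        sigma = a @ a.T * 0.01 + np.eye(9) * 0.01
        model = CovarianceModel(matrix=sigma, masses=np.full(3, 12.0),
                                mass_weighted=True, n_frames=100)
        q_mat = np.linalg.qr(rng.normal(size=(9, 9)))[0]
        rotated = CovarianceModel(matrix=q_mat @ sigma @ q_mat.T,
                                  masses=np.full(3, 12.0),
                                  mass_weighted=True, n_frames=100)
        for fn in (schlitter_entropy, quasiharmonic_entropy):
            assert fn(rotated, dropped_modes=0).value == pytest.approx(
                fn(model, dropped_modes=0).value, rel=1e-6)

    def test_convergence_to_analytic_on_gaussian_fixture(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(30, 30))
        sigma = a @ a.T / 30 + 0.5 * np.eye(30)    # 10-atom molecule, Å²
        traj, analytic = generate_gaussian_trajectory(sigma, n_frames=100_000, seed=7)
        cov = covariance(traj, np.arange(10), window=(0.0, 1e12), fit=False)
        est = quasiharmonic_entropy(cov, dropped_modes=0)
        assert est.value == pytest.approx(analytic["quasiharmonic_J_per_molK"],
                                          rel=0.01)


class TestEntropyDifference:
    def test_identical_models_zero(self):
        model = model_from_eigenvalues([0.1, 0.2, 0.3])
        assert entropy_difference(model, model, dropped_modes=0) == 0.0

    def test_doubled_covariance_closed_form(self):
        lam = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        a = model_from_eigenvalues(2.0 * lam)
        b = model_from_eigenvalues(lam)
        d = len(lam)
        assert entropy_difference(a, b, dropped_modes=0) == pytest.approx(
            0.5 * R * d * np.log(2.0), rel=1e-12)

    def test_sampled_gaussians_match_closed_form(self):
        rng = np.random.default_rng(8)
        variances = rng.uniform(0.5, 1.5, 9)
        rows = [("A", i + 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)) for i in range(3)]
        n = 50000

        def sample(scale, seed):
            r = np.random.default_rng(seed)
            coords = (r.normal(size=(n, 9)) * np.sqrt(scale * variances)
                      ).reshape(n, 3, 3)
            traj = build_trajectory(rows, coords)
            return covariance(traj, np.arange(3), window=(0.0, 1e12),
                              mass_weighted=False, fit=False)

        diff = entropy_difference(sample(2.0, 1), sample(1.0, 2), dropped_modes=0)
        assert diff == pytest.approx(0.5 * R * 9 * np.log(2.0), rel=0.05)

    def test_dimension_mismatch_error(self):
        a = model_from_eigenvalues([0.1, 0.2, 0.3])
        b = model_from_eigenvalues([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        with pytest.raises(ValueError):
            entropy_difference(a, b)


class TestPCA:
    def test_diagonal_first_axis(self):
        model = model_from_eigenvalues([4.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        lam, vec = pca_modes(model, 1)
        assert lam[0] == pytest.approx(4.0)
        assert abs(vec[0, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_planted_two_mode_recovery(self):
        rng = np.random.default_rng(9)
        d = 12
        u1 = rng.normal(size=d); u1 /= np.linalg.norm(u1)
        u2 = rng.normal(size=d); u2 -= u1 * (u1 @ u2); u2 /= np.linalg.norm(u2)
        sigma = 5.0 * np.outer(u1, u1) + 2.0 * np.outer(u2, u2) + 0.01 * np.eye(d)
        model = CovarianceModel(matrix=sigma, masses=np.full(4, 12.0),
                                mass_weighted=True, n_frames=100)
        lam, vec = pca_modes(model, 2)
        assert abs(vec[:, 0] @ u1) > 0.999
        assert abs(vec[:, 1] @ u2) > 0.999
        assert lam[0] >= lam[1]

    def test_full_basis_orthonormal(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(9, 9))
        model = CovarianceModel(matrix=a @ a.T, masses=np.full(3, 12.0),
                                mass_weighted=True, n_frames=100)
        lam, vec = pca_modes(model, 9)
        np.testing.assert_allclose(vec @ vec.T, np.eye(9), atol=1e-8)
        assert np.all(np.diff(lam) <= 1e-12)


class TestProjection:
    def test_static_trajectory_zero_projection(self, eclipsed_traj):
        traj, _ = eclipsed_traj
        idx = select_atoms(traj, chains="A", atom_names="CA")
        cov = covariance(traj, idx, window=(0.0, 4.0), fit=False,
                         mass_weighted=False)
        _, vec = pca_modes(cov, 3)
        proj, _, _ = project_trajectory(traj, cov, vec)
        assert np.abs(proj).max() < 1e-9

    def test_oscillation_along_planted_mode(self):
        rng = np.random.default_rng(11)
        n_atoms, n_frames = 5, 400
        rows = [("A", i + 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)) for i in range(n_atoms)]
        base = rng.normal(size=(n_atoms, 3)) * 5
        mode = rng.normal(size=3 * n_atoms); mode /= np.linalg.norm(mode)
        t = np.linspace(0, 6 * np.pi, n_frames)
        coords = base[None] + (2.0 * np.sin(t)[:, None] * mode[None]).reshape(
            n_frames, n_atoms, 3)
        traj = build_trajectory(rows, coords)
        cov = covariance(traj, np.arange(n_atoms), window=(0.0, 1e9),
                         mass_weighted=False, fit=False)
        lam, vec = pca_modes(cov, 3)
        proj, imin, imax = project_trajectory(traj, cov, vec)
        corr = np.corrcoef(proj[:, 0], np.sin(t))[0, 1]
        assert abs(corr) > 0.999
        assert np.abs(proj[:, 1:]).max() < 1e-6
        assert {imin[0], imax[0]} <= set(np.where(np.abs(np.abs(np.sin(t)) - 1)
                                                  < 1e-3)[0])

    def test_rotation_mode_dominates_vs_wobble(self):
        topo = small_topology()
        spec = small_hexamer_spec(
            n_frames=300, rotation_course=RotationCourse(0.0, 20.0, 40.0), seed=12)
        traj, _ = generate_hexamer_trajectory(spec)
        idx = select_atoms(traj, atom_names="CA",
                           residue_range=topo.com_residue_range)
        cov = covariance(traj, idx, window=(0.0, 1e9), mass_weighted=False)
        lam, vec = pca_modes(cov, 1)
        proj, _, _ = project_trajectory(traj, cov, vec)
        from oligorot import rotation_series
        rot = rotation_series(traj, topo, stats_window=(0.0, 299.0))
        corr = np.corrcoef(proj[:, 0], rot.per_frame_mean)[0, 1]
        assert abs(corr) > 0.9

        wobble_spec = small_hexamer_spec(n_frames=300, wobble_A=0.5, seed=13)
        wtraj, _ = generate_hexamer_trajectory(wobble_spec)
        wcov = covariance(wtraj, idx, window=(0.0, 1e9), mass_weighted=False)
        _, wvec = pca_modes(wcov, 1)
        wproj, _, _ = project_trajectory(wtraj, wcov, wvec)
        wrot = rotation_series(wtraj, topo, stats_window=(0.0, 299.0))
        wcorr = np.corrcoef(wproj[:, 0], wrot.per_frame_mean)[0, 1]
        assert abs(wcorr) < 0.75  # no coordinated rotation mode
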