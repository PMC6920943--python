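import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from surfdyn import (
    EquilibratedWindow,
    ReplicateEnsemble,
    SyntheticSpec,
    Trajectory,
    ca_mask,
    center_ensemble,
    covariance_matrix,
    dccm,
    eigendecompose,
    interpolate_pc_extremes,
    pca,
    select,
    simulate_unbound_ensemble,
)
from surfdyn.correlation import CenteredEnsemble

from conftest import make_two_chain_system


def brute_force_covariance(x):
    """Direct double-loop of C_ij = <dr_i . dr_j> on centered coordinates."""
    f, n, _ = x.shape
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for t in range(f):
                acc += x[t, i] @ x[t, j]
            c[i, j] = acc / f
    return c


@pytest.fixture
def hand_ensemble(duo_system):
    """5 atoms, 10 frames of the chain-B + first chain-A CA selection."""
    rng = np.random.default_rng(8)
    base = np.zeros((duo_system.n_atoms, 3))
    base[:, 0] = 6.0 * np.arange(duo_system.n_atoms)
    base[:, 1] = 0.05 * np.arange(duo_system.n_atoms) ** 2
    coords = base[None] + 0.7 * rng.standard_normal((10, duo_system.n_atoms, 3))
    traj = Trajectory(duo_system, coords, np.arange(10.0))
    ens = ReplicateEnsemble([traj], [EquilibratedWindow(0, 10)])
    mask = select(duo_system, "chain B or (chain A and resid 1)")
    return ens, mask


class TestCovarianceAndDccm:
    def test_matches_brute_force_summation_exactly(self, hand_ensemble):
        ens, mask = hand_ensemble
        centered = center_ensemble(ens, mask=mask)
        cov = covariance_matrix(centered).matrix
        ref = brute_force_covariance(centered.coordinates)
        np.testing.assert_allclose(cov, ref, atol=1e-12)
        m = dccm(centered).matrix
        d = np.sqrt(np.diag(ref))
        np.testing.assert_allclose(m, ref / np.outer(d, d), atol=1e-12)

    def test_normalized_matrix_contract(self, hand_ensemble):
        ens, mask = hand_ensemble
        m = dccm(center_ensemble(ens, mask=mask)).matrix
        np.testing.assert_allclose(np.diag(m), 1.0, atol=0)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert m.min() >= -1.0 and m.max() <= 1.0

    def test_invariant_under_global_rotation_of_all_frames(self, hand_ensemble):
        ens, mask = hand_ensemble
        m1 = dccm(center_ensemble(ens, mask=mask)).matrix
        rot = Rotation.from_euler("xyz", [15, -40, 70], degrees=True).as_matrix()
        traj = ens.trajectories[0]
        rotated = Trajectory(
            traj.system, traj.coordinates @ rot.T + 4.0, traj.times
        )
        ens2 = ReplicateEnsemble([rotated], [EquilibratedWindow(0, 10)])
        # superpose back onto the unrotated reference frame
        m2 = dccm(
            center_ensemble(
                ens2, mask=mask, reference=traj.coordinates[0]
            )
        ).matrix
        np.testing.assert_allclose(m1, m2, atol=1e-8)

    def test_zero_variance_atom_is_reported(self, duo_system):
        coords = np.zeros((5, duo_system.n_atoms, 3))
        coords[:, :, 0] = np.arange(duo_system.n_atoms)[None, :]
        rng = np.random.default_rng(0)
        coords[:, 1:, :] += 0.1 * rng.standard_normal((5, duo_system.n_atoms - 1, 3))
        traj = Trajectory(duo_system, coords, np.arange(5.0))
        ens = ReplicateEnsemble([traj], [EquilibratedWindow(0, 5)])
        mask = select(duo_system, "chain A")
        centered = center_ensemble(ens, mask=mask)
        # zero out atom 0 exactly after centering
        x = centered.coordinates.copy()
        x[:, 0, :] = 0.0
        frozen = CenteredEnsemble(
            x, centered.mean_structure, centered.system, centered.mask,
            centered.frames_per_replicate,
        )
        with pytest.raises(ValueError, match="zero-variance"):
            dccm(frozen)

    def test_single_frame_rejected(self, duo_system):
        rng = np.random.default_rng(1)
        traj = Trajectory(
            duo_system,
            rng.uniform(-5, 5, (1, duo_system.n_atoms, 3)),
            np.zeros(1),
        )
        ens = ReplicateEnsemble([traj], [EquilibratedWindow(0, 1)])
        centered = center_ensemble(ens, mask=select(duo_system, "chain A"))
        with pytest.raises(ValueError, match="2 frames"):
            covariance_matrix(centered)


class TestCentering:
    def test_per_atom_means_vanish(self, hand_ensemble):
        ens, mask = hand_ensemble
        centered = center_ensemble(ens, mask=mask)
        np.testing.assert_allclose(
            centered.coordinates.mean(axis=0), 0.0, atol=1e-12
        )

    def test_pure_rigid_motion_centers_to_zero(self, duo_system):
        base = np.zeros((duo_system.n_atoms, 3))
        base[:, 0] = 4.0 * np.arange(duo_system.n_atoms)
        base[:, 1] = 0.1 * np.arange(duo_system.n_atoms) ** 2
        frames = [
            base @ Rotation.from_euler("z", a, degrees=True).as_matrix().T + a
            for a in (0.0, 45.0, 170.0)
        ]
        traj = Trajectory(duo_system, np.stack(frames), np.arange(3.0))
        ens = ReplicateEnsemble([traj], [EquilibratedWindow(0, 3)])
        centered = center_ensemble(ens, mask=select(duo_system, "chain A"))
        np.testing.assert_allclose(centered.coordinates, 0.0, atol=1e-8)

    def test_mask_restricts_output_atoms(self, hand_ensemble):
        ens, mask = hand_ensemble
        centered = center_ensemble(ens, mask=mask)
        assert centered.coordinates.shape[1] == len(mask)

    def test_windows_must_be_set(self, hand_ensemble):
        ens, mask = hand_ensemble
        bare = ReplicateEnsemble(ens.trajectories)
        with pytest.raises(ValueError, match="windows"):
            center_ensemble(bare, mask=mask)


class TestEigendecomposition:
    def test_identity_matrix(self):
        res = eigendecompose(np.eye(4))
        np.testing.assert_allclose(res.eigenvalues, 1.0)

    def test_rank_one_matrix(self):
        v = np.array([1.0, -2.0, 3.0])
        res = eigendecompose(np.outer(v, v))
        assert res.eigenvalues[0] == pytest.approx(v @ v)
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-12)

    def test_reconstruction_on_random_symmetric(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((30, 30))
        sym = 0.5 * (a + a.T)
        res = eigendecompose(sym)
        recon = res.eigenvectors @ np.diag(res.eigenvalues) @ res.eigenvectors.T
        assert np.abs(sym - recon).max() < 1e-8
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(
            res.eigenvectors.T @ res.eigenvectors, np.eye(30), atol=1e-10
        )

    def test_asymmetric_input_rejected(self):
        m = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(m)


class TestPca:
    def test_variance_bookkeeping(self, hand_ensemble):
        ens, mask = hand_ensemble
        centered = center_ensemble(ens, mask=mask)
        res = pca(centered)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        total = (centered.coordinates**2).sum(axis=(1, 2)).mean()
        assert res.eigen.eigenvalues.sum() == pytest.approx(total, rel=1e-10)
        proj_var = res.projections.var(axis=0, ddof=0)
        np.testing.assert_allclose(
            proj_var, np.maximum(res.eigen.eigenvalues, 0.0), atol=1e-10
        )
        per_pc = res.residue_contributions.sum(axis=0)
        np.testing.assert_allclose(per_pc.to_numpy(), 1.0, atol=1e-10)

    def test_planted_collective_motion_dominates_pc1(self):
        spec = SyntheticSpec(
            domain_blocks=((0, 6, "D1"),),
            planted_interfacial=(),
            planted_allosteric={},
            correlation_plan=(),
            moving_blocks=("D1",),
            noise_sigma=0.02,
            n_frames=400,
            n_replicates=2,
            seed=5,
        )
        ens = simulate_unbound_ensemble(spec)
        res = pca(center_ensemble(ens, mask=ca_mask(ens.system)))
        assert res.variance_fraction[0] > 0.95
        top = res.residue_contributions["PC1"].sort_values(ascending=False)
        assert set(top.index[:6]) == {f"A:{i}" for i in range(1, 7)}

    def test_planted_block_correlations_recovered(self):
        blocks = ((0, 6, "D1"), (6, 12, "D2"), (12, 18, "D3"))
        spec = SyntheticSpec(
            domain_blocks=blocks,
            planted_interfacial=(),
            planted_allosteric={},
            correlation_plan=(("D1", "D2", 0.9), ("D1", "D3", 0.0)),
            moving_blocks=("D1", "D2", "D3"),
            n_frames=2000,
            n_replicates=4,
            seed=3,
        )
        ens = simulate_unbound_ensemble(spec)
        cam = ca_mask(ens.system)
        fit = select(ens.system, "resid 19-30").intersection(cam)
        m = dccm(center_ensemble(ens, mask=cam, fit_mask=fit)).matrix
        d12 = m[np.ix_(range(0, 6), range(6, 12))].mean()
        d13 = m[np.ix_(range(0, 6), range(12, 18))].mean()
        assert d12 == pytest.approx(0.9, abs=0.1)
        assert d13 == pytest.approx(0.0, abs=0.1)


class TestInterpolation:
    def test_endpoints_midpoint_and_monotonicity(self, hand_ensemble):
        ens, mask = hand_ensemble
        centered = center_ensemble(ens, mask=mask)
        res = pca(centered)
        traj = interpolate_pc_extremes(res, 0, n_steps=5)
        assert traj.n_frames == 5
        vec = res.eigen.eigenvectors[:, 0]
        proj = (
            (traj.coordinates - centered.mean_structure[None])
            .reshape(5, -1) @ vec
        )
        assert proj[0] == pytest.approx(res.projections[:, 0].min())
        assert proj[-1] == pytest.approx(res.projections[:, 0].max())
        assert np.all(np.diff(proj) > 0)
        np.testing.assert_allclose(
            traj.coordinates[2],
            0.5 * (traj.coordinates[0] + traj.coordinates[-1]),
            atol=1e-10,
        )

    def test_two_steps_equal_extreme_reconstructions(self, hand_ensemble):
        ens, mask = hand_ensemble
        res = pca(center_ensemble(ens, mask=mask))
        traj = interpolate_pc_extremes(res, 0, n_steps=2)
        assert traj.n_frames == 2
        with pytest.raises(ValueError):
            interpolate_pc_extremes(res, 0, n_steps=1)
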