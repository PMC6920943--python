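import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surfdyn import (
    SyntheticSpec,
    Trajectory,
    build_toy_receptor,
    filter_buried,
    jackknife_mean_sem,
    relative_sasa,
    sphere_points,
    trajectory_residue_sasa,
)
from surfdyn.sasa import atom_sasa, _apply_rule, sasa_frames


def two_sphere_reference(r1, r2, d, probe):
    """Analytic SASA of two intersecting spheres (spherical-cap formula)."""
    R1, R2 = r1 + probe, r2 + probe
    areas = np.array([4 * np.pi * R1**2, 4 * np.pi * R2**2])
    if d >= R1 + R2:
        return areas
    if d <= abs(R1 - R2):  # one sphere swallowed
        if R1 < R2:
            return np.array([0.0, areas[1]])
        return np.array([areas[0], 0.0])
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return areas - 2 * np.pi * np.array([R1 * h1, R2 * h2])


class TestEngine:
    def test_sphere_points_unit_norm_and_vanishing_mean(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) <= 0.05
        assert sphere_points(1).shape == (1, 3)

    def test_isolated_atom_matches_closed_form(self):
        sasa = atom_sasa(np.zeros((1, 3)), np.array([1.7]))
        expected = 4 * np.pi * 3.1**2
        assert sasa[0] == pytest.approx(expected, rel=1e-9)

    def test_two_sphere_cap_formula(self):
        rng = np.random.default_rng(0)
        probe = 1.4
        for _ in range(20):
            r1, r2 = rng.uniform(1.2, 2.0, size=2)
            lo = abs(r1 - r2) + 0.2
            hi = r1 + r2 + 2 * probe - 0.2
            d = rng.uniform(lo, hi)
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            got = atom_sasa(coords, np.array([r1, r2]), probe_radius=probe)
            want = two_sphere_reference(r1, r2, d, probe)
            full = 4 * np.pi * (max(r1, r2) + probe) ** 2
            np.testing.assert_allclose(got, want, atol=0.02 * full)

    def test_fully_enclosed_atom_has_zero_sasa(self):
        shell = 2.0 * sphere_points(60)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.7)
        assert atom_sasa(coords, radii)[0] == 0.0

    def test_atoms_outside_mask_are_invisible(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        alone = atom_sasa(coords, radii, mask=np.array([0]))
        assert alone[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-9)
        assert alone[1] == 0.0  # excluded atom receives no SASA

    def test_occlusion_monotonicity(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 14)
            coords = rng.uniform(-4, 4, size=(n, 3))
            radii = rng.uniform(1.2, 2.0, size=n)
            base = atom_sasa(coords, radii)
            extra = np.vstack([coords, rng.uniform(-4, 4, size=(1, 3))])
            radii2 = np.append(radii, rng.uniform(1.2, 2.0))
            after = atom_sasa(extra, radii2)
            assert np.all(after[:n] <= base + 1e-9)

    def test_agrees_with_independent_shrake_rupley(self):
        import biotite.structure as struc

        rng = np.random.default_rng(3)
        coords = rng.uniform(-5, 5, size=(25, 3))
        radii = np.full(25, 1.7)
        ours = atom_sasa(coords, radii, n_points=1000)
        arr = struc.AtomArray(25)
        arr.coord = coords.astype(np.float32)
        arr.chain_id = np.full(25, "A")
        arr.res_id = np.arange(1, 26)
        arr.res_name = np.full(25, "GLY")
        arr.atom_name = np.full(25, "CA")
        arr.element = np.full(25, "C")
        theirs = struc.sasa(
            arr, probe_radius=1.4, vdw_radii=radii, point_number=1000
        )
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.02)

    def test_quadrature_error_shrinks_with_more_points(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        want = two_sphere_reference(1.7, 1.7, 2.5, 1.4)
        errors = [
            np.abs(atom_sasa(coords, radii, n_points=n) - want).max()
            for n in (60, 240, 960)
        ]
        assert errors[2] < errors[0]


class TestTrajectoryAveraging:
    def test_static_trajectory_equals_single_frame(self, small_spec):
        system, ref = build_toy_receptor(small_spec)
        traj = Trajectory(system, np.stack([ref] * 3), np.arange(3.0))
        avg = trajectory_residue_sasa(traj)
        single = trajectory_residue_sasa(
            Trajectory(system, ref[None], np.zeros(1))
        )
        pd.testing.assert_series_equal(avg, single)

    def test_stride_selects_alternating_state(self, small_spec):
        system, ref = build_toy_receptor(small_spec)
        state_b = ref + np.array([50.0, 0.0, 0.0])  # far-shifted state
        coords = np.stack([ref, state_b, ref, state_b])
        traj = Trajectory(system, coords, np.arange(4.0))
        strided = trajectory_residue_sasa(traj, stride=2)
        only_a = trajectory_residue_sasa(
            Trajectory(system, ref[None], np.zeros(1))
        )
        pd.testing.assert_series_equal(strided, only_a)

    def test_window_mean_is_linear(self, small_spec):
        system, ref = build_toy_receptor(small_spec)
        rng = np.random.default_rng(0)
        coords = ref[None] + 0.1 * rng.standard_normal((4, system.n_atoms, 3))
        traj = Trajectory(system, coords, np.arange(4.0))
        whole = trajectory_residue_sasa(traj)
        per_frame = [
            trajectory_residue_sasa(traj, window=(f, f + 1)) for f in range(4)
        ]
        np.testing.assert_allclose(
            whole.to_numpy(),
            np.mean([s.to_numpy() for s in per_frame], axis=0),
            rtol=1e-12,
        )

    def test_empty_window_rejected(self, small_spec):
        system, ref = build_toy_receptor(small_spec)
        traj = Trajectory(system, ref[None], np.zeros(1))
        with pytest.raises(ValueError, match="window"):
            trajectory_residue_sasa(traj, window=(1, 1))


class TestRelativeSasa:
    def test_percent_conversion_endpoints(self):
        values = pd.Series([104.0, 0.0], index=["A:1", "A:2"])
        names = {"A:1": "GLY", "A:2": "GLY"}
        rel = relative_sasa(values, names)  # GLY max = 104 A^2
        assert rel.tolist() == [100.0, 0.0]

    def test_missing_residue_type_errors_with_name(self):
        values = pd.Series([10.0], index=["A:1"])
        with pytest.raises(KeyError, match="XYZ"):
            relative_sasa(values, {"A:1": "XYZ"})

    def test_above_hundred_warns_but_not_clipped(self):
        values = pd.Series([120.0], index=["A:1"])
        with pytest.warns(UserWarning, match="above 100"):
            rel = relative_sasa(values, {"A:1": "GLY"})
        assert rel.iloc[0] > 100.0


class TestJackknife:
    def test_constant_replicates_have_zero_sem(self):
        mean, sem = jackknife_mean_sem(np.array([5.0, 5.0, 5.0, 5.0]))
        assert (mean, sem) == (5.0, 0.0)

    def test_known_example(self):
        mean, sem = jackknife_mean_sem(np.array([1.0, 2.0, 3.0, 4.0]))
        assert mean == pytest.approx(2.5)
        # for the plain mean, jack-knife SEM equals s/sqrt(n)
        assert sem == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2.0)

    def test_permutation_invariance(self):
        values = np.array([3.1, 0.2, 7.7, 5.0, 1.4])
        m1, s1 = jackknife_mean_sem(values)
        m2, s2 = jackknife_mean_sem(values[::-1].copy())
        assert m1 == pytest.approx(m2) and s1 == pytest.approx(s2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e4, 1e4, allow_nan=False), min_size=2, max_size=12
        )
    )
    def test_equals_standard_error_of_mean(self, values):
        values = np.asarray(values)
        _, sem = jackknife_mean_sem(values)
        expected = np.std(values, ddof=1) / np.sqrt(len(values))
        assert sem == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            jackknife_mean_sem(np.array([1.0]))


class TestThresholdRules:
    def test_burial_filter_boundary(self):
        stats = pd.DataFrame(
            {
                "residue_key": ["A:1", "A:2", "A:3"],
                "relative_sasa_mean": [19.9, 20.0, 55.0],
            }
        )
        assert filter_buried(stats) == {"A:2", "A:3"}
        assert filter_buried(stats.iloc[:0]) == set()

    def test_sem_rule_and_delta_threshold(self):
        keys = ["A:1", "A:2", "A:3", "A:4"]
        names = {k: "BEA" for k in keys}
        delta = np.array([8.0, 8.0, 4.9, -12.0])
        sem = np.array([9.0, 7.0, 0.1, 2.0])
        ref = np.full(4, 50.0)
        report = _apply_rule(
            delta, sem, keys, names, ref, ref + delta, set(keys),
            delta_min=5.0, sem_rule=True, classification="interfacial",
        )
        # A:1 fails the SEM rule, A:3 fails the 5-point threshold
        assert report["residue_key"].tolist() == ["A:2", "A:4"]
        assert report.set_index("residue_key").loc["A:4", "direction"] == "occluded"

    def test_burial_filter_gates_reporting(self):
        keys = ["A:1"]
        report = _apply_rule(
            np.array([10.0]), np.array([0.5]), keys, {"A:1": "BEA"},
            np.array([10.0]), np.array([20.0]), retained=set(),
            delta_min=5.0, sem_rule=True, classification="allosteric",
        )
        assert report.empty
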