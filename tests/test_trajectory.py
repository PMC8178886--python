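"""Superposition, RMSD/RMSF, delta-RMSF flagging, regions and PCA."""

import numpy as np
import pytest

from enzstab import (
    FluctuationProfile,
    Trajectory,
    TrajectorySpec,
    delta_rmsf,
    find_regions,
    flag_fluctuating,
    generate_trajectory,
    pca_ca,
    read_multimodel_pdb,
    read_xyz,
    rmsd_series,
    rmsf_per_residue,
    superpose,
    write_multimodel_pdb,
    write_xyz,
)


def _rotz(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestSuperpose:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        x = np.random.default_rng(1).normal(size=(12, 3))
        moved = x @ _rotz(np.pi / 2).T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = superpose(moved, x)
        assert rmsd < 1e-8

    def test_proper_rotation_enforced(self):
        x = np.random.default_rng(2).normal(size=(8, 3))
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        R, _, _ = superpose(mirrored, x)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_four_atom_toy_against_rotation_grid_oracle(self):
        """Exhaustive scan over z-rotations bounds the optimum for a planar
        toy: the Kabsch RMSD must match the best grid value."""
        ref = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
        mobile = ref @ _rotz(0.7).T + 0.05 * np.array(
            [[1, 0, 0], [0, -1, 0], [-1, 0, 0], [0, 1, 0]], dtype=float)
        _, _, rmsd = superpose(mobile, ref)
        best = min(
            np.sqrt(np.mean(np.sum((mobile @ _rotz(a).T - ref) ** 2, axis=1)))
            for a in np.linspace(-np.pi, np.pi, 100_000)
        )
        assert rmsd <= best + 1e-6
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line + 0.1, line)


class TestRMSD:
    def test_static_trajectory_is_zero(self):
        spec = TrajectorySpec(n_residues=10, n_frames=5,
                              amplitude_profile=(0.0,) * 10, seed=0)
        series = rmsd_series(generate_trajectory(spec))
        assert np.allclose(series, 0.0, atol=1e-12)

    def test_gaussian_trajectory_matches_closed_form(self):
        # per-coordinate SD sigma => E[RMSD^2] ~ 2*3*sigma^2 against a noisy
        # first-frame reference, shrunk by the 6 rigid dof the fit absorbs
        sigma, n_res, n_frames = 0.4, 60, 400
        spec = TrajectorySpec(n_residues=n_res, n_frames=n_frames,
                              amplitude_profile=(sigma,) * n_res, seed=8)
        traj = generate_trajectory(spec)
        series = rmsd_series(traj)[1:]
        n_atoms = traj.n_atoms
        expected = sigma * np.sqrt(2 * 3) * np.sqrt(1 - 6 / (3 * n_atoms))
        assert np.mean(series) == pytest.approx(expected, rel=0.03)

    def test_stochastically_monotone_in_amplitude(self):
        mk = lambda a, s: rmsd_series(generate_trajectory(
            TrajectorySpec(n_residues=20, n_frames=100,
                           amplitude_profile=(a,) * 20, seed=s)))
        assert np.mean(mk(0.8, 3)) > np.mean(mk(0.2, 3))

    def test_rigid_body_motion_invariance(self):
        base = TrajectorySpec(n_residues=15, n_frames=50,
                              amplitude_profile=(0.3,) * 15, seed=5)
        jittered = TrajectorySpec(n_residues=15, n_frames=50,
                                  amplitude_profile=(0.3,) * 15, seed=5,
                                  rigid_body_motion=True)
        a = rmsd_series(generate_trajectory(base))
        b = rmsd_series(generate_trajectory(jittered))
        assert np.allclose(a, b, atol=1e-8)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        spec = TrajectorySpec(n_residues=8, n_frames=4,
                              amplitude_profile=(0.0,) * 8, seed=0)
        prof = rmsf_per_residue(generate_trajectory(spec))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_rotated_static_structure_superposes_to_zero(self):
        spec = TrajectorySpec(n_residues=8, n_frames=10,
                              amplitude_profile=(0.0,) * 8, seed=1,
                              rigid_body_motion=True)
        prof = rmsf_per_residue(generate_trajectory(spec))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-8)

    def test_isotropic_moment_identity(self):
        # per-coordinate SD sigma => per-atom RMSF -> sigma*sqrt(3), with the
        # finite-sample shrink sqrt(1 - 6/(3N) - 1/F) from the 6 rigid dof
        # and the estimated mean structure
        sigma, n_res, F = 0.3, 100, 1000
        spec = TrajectorySpec(n_residues=n_res, n_frames=F,
                              amplitude_profile=(sigma,) * n_res, seed=11)
        traj = generate_trajectory(spec)
        prof = rmsf_per_residue(traj)
        expected = sigma * np.sqrt(3) * np.sqrt(1 - 6 / (3 * traj.n_atoms) - 1 / F)
        se = prof.rmsf.std(ddof=1) / np.sqrt(n_res)
        assert abs(prof.rmsf.mean() - expected) < 3 * se

    def test_amplitude_scaling_doubles_rmsf(self):
        amp = [0.2] * 30
        amp[14] = 0.4
        spec = TrajectorySpec(n_residues=30, n_frames=2000,
                              amplitude_profile=tuple(amp), seed=13)
        prof = rmsf_per_residue(generate_trajectory(spec))
        others = np.delete(prof.rmsf, 14).mean()
        assert prof.rmsf[14] / others == pytest.approx(2.0, rel=0.05)

    def test_rank_correlation_with_amplitude_profile(self):
        from scipy import stats
        rng = np.random.default_rng(21)
        amp = tuple(rng.uniform(0.1, 0.8, 40))
        spec = TrajectorySpec(n_residues=40, n_frames=1000,
                              amplitude_profile=amp, seed=22)
        prof = rmsf_per_residue(generate_trajectory(spec))
        rho = stats.spearmanr(amp, prof.rmsf).statistic
        assert rho > 0.95


class TestDeltaRMSFAndRegions:
    def _profile(self, values, temp):
        ids = np.arange(1, len(values) + 1)
        return FluctuationProfile(residue_ids=ids, rmsf=np.asarray(values, float),
                                  temperature=temp)

    def test_base_against_itself_is_zero(self):
        base = self._profile([0.5, 0.7, 0.6], 241.0)
        d = delta_rmsf(base, base)
        assert np.allclose(d.delta_rmsf, 0.0)
        assert len(flag_fluctuating([d], cutoff=0.5)) == 0

    def test_constructed_exceedances_flagged_exactly(self):
        """Residues 159 and 160 (of a 200-residue construction) spread past
        the 0.5 A cutoff across the three delta profiles; nothing else does."""
        n = 200
        base = self._profile([0.5] * n, 241.0)
        rng = np.random.default_rng(0)
        deltas = []
        for temp, bump in [(278.0, 0.9), (298.0, 1.6), (314.0, 2.4)]:
            vals = np.full(n, 0.5) + rng.uniform(-0.05, 0.05, n)
            vals[158] += bump       # residue id 159
            vals[159] += bump * 1.1  # residue id 160
            deltas.append(delta_rmsf(self._profile(vals, temp), base))
        flagged = flag_fluctuating(deltas, cutoff=0.5)
        assert set(flagged.tolist()) == {159, 160}

    def test_infinite_cutoff_flags_nothing(self):
        base = self._profile([0.5] * 10, 241.0)
        hot = self._profile([5.0] * 10, 314.0)
        d = delta_rmsf(hot, base)
        assert len(flag_fluctuating([d, d], cutoff=np.inf)) == 0

    def test_find_regions_rules(self):
        assert find_regions([159, 160, 161], gap_tolerance=1) == [(159, 161)]
        assert find_regions([], gap_tolerance=1) == []
        assert find_regions([10, 12], gap_tolerance=1, min_size=1) == [(10, 12)]
        assert find_regions([10, 12], gap_tolerance=0, min_size=1) == [(10, 10), (12, 12)]
        # isolated flags below min_size are dropped
        assert find_regions([10, 50], gap_tolerance=2, min_size=2) == []


class TestPCA:
    def test_two_mode_toy_proportions(self):
        """Two torque-free stretch modes with sample variances 4:1 give
        variance proportions exactly (0.8, 0.2)."""
        ref = np.array([[5.0, 0, 0], [-5.0, 0, 0], [0, 5.0, 0], [0, -5.0, 0]])
        mode1 = np.array([[1, 0, 0], [-1, 0, 0], [0, 0, 0], [0, 0, 0]]) / np.sqrt(2)
        mode2 = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 0], [0, -1, 0]]) / np.sqrt(2)
        c1 = [2.0, -2.0, 2.0, -2.0]
        c2 = [1.0, -1.0, -1.0, 1.0]
        coords = np.array([ref + a * mode1 + b * mode2 for a, b in zip(c1, c2)])
        traj = Trajectory(coords, np.array(["CA"] * 4, dtype=object),
                          np.arange(1, 5))
        res = pca_ca(traj, k=2)
        assert res.variance_proportions == pytest.approx([0.8, 0.2], abs=1e-10)

    def test_isotropic_fluctuations_spread_evenly(self):
        spec = TrajectorySpec(n_residues=6, atoms_per_residue=1, n_frames=4000,
                              amplitude_profile=(0.5,) * 6, seed=3)
        traj = generate_trajectory(spec)
        traj.atom_names = np.array(["CA"] * 6, dtype=object)
        res = pca_ca(traj, k=5)
        # 18 coordinates minus 6 rigid dof leave ~12 comparable modes
        ratio = res.eigenvalues[0] / res.eigenvalues[4]
        assert ratio < 1.5

    def test_svd_oracle_equivalence(self, gaussian_traj):
        _, traj = gaussian_traj
        res = pca_ca(traj, k=5)
        # independent route: SVD of the centered, superposed Calpha matrix
        from enzstab.trajectory import _mean_fitted
        sel = traj.selection(["CA"])
        sub = Trajectory(traj.coords[:, sel, :], traj.atom_names[sel],
                         traj.residue_ids[sel])
        fitted, mean = _mean_fitted(sub, np.ones(sub.n_atoms, bool))
        X = fitted.reshape(sub.n_frames, -1) - mean.reshape(-1)
        svals = np.linalg.svd(X, compute_uv=False)
        lam = svals**2 / (sub.n_frames - 1)
        assert np.allclose(res.eigenvalues, lam[:5], rtol=1e-8, atol=1e-10)

    def test_invariants(self, gaussian_traj):
        _, traj = gaussian_traj
        res = pca_ca(traj, k=5)
        p = res.variance_proportions
        assert np.all(p >= 0) and np.all(p <= 1) and p.sum() <= 1 + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.allclose(res.residue_contributions.sum(axis=0), 1.0)

    def test_k_beyond_rank_rejected(self):
        spec = TrajectorySpec(n_residues=10, n_frames=3, seed=0)
        with pytest.raises(ValueError, match="rank"):
            pca_ca(generate_trajectory(spec), k=5)


class TestIO:
    def test_pdb_round_trip(self, tmp_path):
        spec = TrajectorySpec(n_residues=6, n_frames=4,
                              amplitude_profile=(0.3,) * 6, seed=2)
        traj = generate_trajectory(spec)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path, temperature=298.0)
        assert back.n_frames == 4 and back.n_atoms == traj.n_atoms
        # PDB coordinates carry 3 decimals
        assert np.allclose(back.coords, traj.coords, atol=1.5e-3)
        assert np.array_equal(back.residue_ids, traj.residue_ids)

    def test_xyz_round_trip(self, tmp_path):
        spec = TrajectorySpec(n_residues=5, n_frames=3, seed=4,
                              temperature=278.0)
        traj = generate_trajectory(spec)
        write_xyz(traj, tmp_path / "t.xyz", tmp_path / "t.map.json")
        back = read_xyz(tmp_path / "t.xyz", tmp_path / "t.map.json")
        assert np.allclose(back.coords, traj.coords, atol=1e-5)
        assert back.temperature == 278.0
        assert np.array_equal(back.residue_ids, traj.residue_ids)
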