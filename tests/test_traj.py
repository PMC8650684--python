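from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from deepvs.synthdata import generate_hills, generate_trajectory, write_hills
from deepvs.traj import (FESGrid, HBondCriteria, HillsLog, Trajectory,
                         default_grid, hbond_series, kabsch_superpose,
                         read_hills, read_multimodel_pdb, reconstruct_fes,
                         rmsd_series, stability_rank, write_fes,
                         write_multimodel_pdb)


def _traj_from_frames(frames, **selections):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(times=np.arange(len(frames), dtype=float),
                      coords=frames, elements=["C"] * frames.shape[1],
                      **selections)


class TestRmsdSeries:
    def test_identical_frames_zero(self, rng):
        ref = rng.normal(size=(10, 3))
        traj = _traj_from_frames([ref] * 5, ligand_atoms=[7, 8, 9],
                                 calpha_atoms=list(range(7)))
        assert all(r == pytest.approx(0.0) for _, r in rmsd_series(traj))

    def test_rigid_motion_removed(self, rng):
        ref = rng.normal(size=(10, 3))
        frames = [ref]
        for _ in range(4):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            frames.append(ref @ R.T + rng.uniform(-5, 5, size=3))
        traj = _traj_from_frames(frames, ligand_atoms=[7, 8, 9],
                                 calpha_atoms=list(range(7)))
        for _, r in rmsd_series(traj):
            assert r == pytest.approx(0.0, abs=1e-9)

    def test_known_displacement(self):
        ref = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], float)
        moved = ref.copy()
        moved[3] = [0, 0, 6]  # one atom displaced 2 Å along a frame axis
        traj = _traj_from_frames([ref, moved])
        # superpose on the three fixed atoms, measure the displaced one
        series = rmsd_series(traj, measure_selection=[3],
                             superpose_selection=[0, 1, 2])
        assert series[1][1] == pytest.approx(2.0, abs=1e-9)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_matches_mdanalysis_superposition_oracle(self, seed):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(seed)
        ref = rng.normal(scale=4.0, size=(10, 3))
        frame = ref + rng.normal(scale=1.0, size=(10, 3))
        traj = _traj_from_frames([ref, frame])
        ours = rmsd_series(traj, measure_selection=list(range(10)),
                           superpose_selection=list(range(10)))[1][1]
        theirs = mda_rms.rmsd(frame, ref, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_superposition_never_increases_rmsd(self, rng):
        ref = rng.normal(scale=4.0, size=(8, 3))
        frame = ref + rng.normal(scale=2.0, size=(8, 3))
        traj = _traj_from_frames([ref, frame])
        after = rmsd_series(traj, measure_selection=list(range(8)),
                            superpose_selection=list(range(8)))[1][1]
        before = float(np.sqrt(((frame - ref) ** 2).sum() / 8))
        assert after <= before + 1e-12

    def test_selection_size_guard(self, rng):
        traj = _traj_from_frames([rng.normal(size=(5, 3))] * 2)
        with pytest.raises(ValueError):
            rmsd_series(traj, measure_selection=[0], superpose_selection=[1, 2])


def _hbond_frame(d_on=2.8):
    # donor N at origin, H on the x axis, acceptor O beyond it (linear)
    return np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [d_on, 0.0, 0.0]])


class TestHbondSeries:
    def _traj(self, frames):
        frames = np.asarray(frames, dtype=float)
        return Trajectory(times=np.arange(len(frames), dtype=float),
                          coords=frames, elements=["N", "H", "O"],
                          donors=[(0, 1)], acceptors=[2])

    def test_linear_geometry_counts(self):
        traj = self._traj([_hbond_frame(2.8)])
        assert hbond_series(traj) == [(0.0, 1)]

    def test_long_distance_rejected(self):
        traj = self._traj([_hbond_frame(4.5)])
        assert hbond_series(traj, HBondCriteria(d_max=3.5)) == [(0.0, 0)]

    def test_bent_angle_rejected(self):
        frame = _hbond_frame(2.8)
        frame[2] = [1.0, 1.8, 0.0]  # acceptor beside the hydrogen, ~90°
        traj = self._traj([frame])
        assert hbond_series(traj, HBondCriteria(angle_min=130.0)) == [(0.0, 0)]

    def test_rotation_translation_invariant(self, rng):
        frame = _hbond_frame(2.8)
        R = Rotation.random(random_state=7).as_matrix()
        moved = frame @ R.T + np.array([3.0, -2.0, 5.0])
        assert hbond_series(self._traj([moved])) == [(0.0, 1)]

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_matches_triple_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        frame = rng.uniform(0, 8, size=(n, 3))
        donors = [(0, 1), (4, 5), (8, 9)]
        acceptors = [2, 3, 6, 12, 15]
        crit = HBondCriteria(d_max=3.5, angle_min=120.0)
        traj = Trajectory(times=[0.0], coords=frame[None], elements=["C"] * n,
                          donors=donors, acceptors=acceptors)
        expected = 0
        for d, h in donors:
            for a in acceptors:
                if a in (d, h):
                    continue
                if np.linalg.norm(frame[a] - frame[d]) > crit.d_max:
                    continue
                v1, v2 = frame[d] - frame[h], frame[a] - frame[h]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) >= crit.angle_min:
                    expected += 1
        assert hbond_series(traj, crit)[0][1] == expected

    def test_empty_selection_raises(self, rng):
        traj = _traj_from_frames([rng.normal(size=(4, 3))])
        with pytest.raises(ValueError):
            hbond_series(traj)


class TestReconstructFes:
    def test_single_hill_minimum_at_center(self):
        hills = HillsLog(times=[0.0], centers=[1.0], sigmas=[0.1], heights=[2.0])
        fes = reconstruct_fes(hills, np.linspace(0, 2, 2001))
        s_min, f_min = fes.minimum()
        assert s_min == pytest.approx(1.0, abs=1e-3)
        assert f_min == pytest.approx(-2.0, abs=1e-9)

    def test_two_equal_hills_symmetric(self):
        hills = HillsLog(times=[0, 1], centers=[-1.0, 1.0],
                         sigmas=[0.2, 0.2], heights=[1.0, 1.0])
        grid = np.linspace(-3, 3, 601)
        fes = reconstruct_fes(hills, grid)
        np.testing.assert_allclose(fes.values, fes.values[::-1], atol=1e-12)

    def test_matches_double_loop_oracle(self):
        hills = generate_hills(n=500, seed=11)
        grid = np.linspace(-1, 4, 1000)
        fes = reconstruct_fes(hills, grid)
        expected = np.zeros_like(grid)
        for s_k, sig, h in zip(hills.centers, hills.sigmas, hills.heights):
            for i, s in enumerate(grid):
                expected[i] -= h * np.exp(-(s - s_k) ** 2 / (2 * sig ** 2))
        np.testing.assert_allclose(fes.values, expected, atol=1e-12)

    def test_linear_in_hills(self):
        h1 = generate_hills(n=40, seed=1)
        h2 = generate_hills(n=60, seed=2)
        both = HillsLog(times=np.concatenate([h1.times, h2.times + 100]),
                        centers=np.concatenate([h1.centers, h2.centers]),
                        sigmas=np.concatenate([h1.sigmas, h2.sigmas]),
                        heights=np.concatenate([h1.heights, h2.heights]))
        grid = np.linspace(-1, 4, 256)
        f_sum = (reconstruct_fes(h1, grid).values
                 + reconstruct_fes(h2, grid).values)
        np.testing.assert_allclose(reconstruct_fes(both, grid).values, f_sum,
                                   atol=1e-12)

    def test_shift_min_to_zero(self):
        hills = generate_hills(n=20, seed=3)
        fes = reconstruct_fes(hills, shift_min_to_zero=True)
        assert fes.values.min() == pytest.approx(0.0, abs=1e-15)
        assert (fes.values >= 0).all()

    def test_hills_file_roundtrip(self, tmp_path):
        hills = generate_hills(n=25, seed=4)
        path = write_hills(hills, tmp_path / "HILLS")
        back = read_hills(path)
        np.testing.assert_allclose(back.centers, hills.centers, rtol=1e-9)
        grid = np.linspace(-1, 4, 128)
        np.testing.assert_allclose(reconstruct_fes(back, grid).values,
                                   reconstruct_fes(hills, grid).values,
                                   atol=1e-7)

    def test_empty_hills_rejected(self):
        with pytest.raises(ValueError):
            HillsLog(times=[], centers=[], sigmas=[], heights=[])
        with pytest.raises(ValueError):
            generate_hills(n=0)


class TestStabilityRank:
    def test_flat_zero_series_ranks_first(self):
        series = {"noisy": [(0, 1.0), (1, 2.0)],
                  "flat": [(0, 0.0), (1, 0.0)],
                  "drift": [(0, 2.0), (1, 6.0)]}
        assert stability_rank(series, 3) == ["flat", "noisy", "drift"]

    def test_k_equals_n_returns_all_sorted(self):
        series = {"a": [(0, 3.0)], "b": [(0, 1.0)]}
        assert stability_rank(series, 2) == ["b", "a"]

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            stability_rank({"a": [(0, 1.0)]}, 2)

    def test_stable_trajectories_outrank_drifting(self):
        series = {}
        for i in range(4):
            traj = generate_trajectory("stable", n_frames=60, seed=i)
            series[f"stable{i}"] = rmsd_series(traj)
        for i in range(4):
            traj = generate_trajectory("drifting", n_frames=60, seed=100 + i)
            series[f"drift{i}"] = rmsd_series(traj)
        top = stability_rank(series, 4)
        assert all(name.startswith("stable") for name in top)


class TestGenerators:
    def test_stable_zero_noise_zero_rmsd(self):
        traj = generate_trajectory("stable", n_frames=10, noise=0.0, seed=0)
        assert all(r == pytest.approx(0.0, abs=1e-9)
                   for _, r in rmsd_series(traj))

    def test_drift_accumulates_to_expected_displacement(self):
        traj = generate_trajectory("drifting", n_frames=100, noise=0.05,
                                   drift=0.1, seed=1)
        final = rmsd_series(traj)[-1][1]
        # 99 frames of 0.1 Å/frame cumulative drift
        assert final == pytest.approx(9.9, abs=0.5)

    def test_same_seed_reproducible(self):
        t1 = generate_trajectory("drifting", n_frames=20, seed=9)
        t2 = generate_trajectory("drifting", n_frames=20, seed=9)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_hills_generator_seeded_and_in_range(self):
        h1 = generate_hills(n=50, seed=5)
        h2 = generate_hills(n=50, seed=5)
        np.testing.assert_array_equal(h1.centers, h2.centers)
        assert ((h1.centers >= 0) & (h1.centers <= 3)).all()
        assert ((h1.sigmas >= 0.05) & (h1.sigmas <= 0.3)).all()

    def test_trajectory_pdb_roundtrip(self, tmp_path):
        traj = generate_trajectory("stable", n_frames=5, seed=2)
        path = write_multimodel_pdb(traj, tmp_path / "t.pdb")
        back = read_multimodel_pdb(path)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)


def test_fes_file_output(tmp_path):
    fes = FESGrid(grid=np.array([0.0, 1.0]), values=np.array([-1.0, 0.0]))
    path = write_fes(fes, tmp_path / "fes.dat")
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("#")
    assert len(lines) == 3
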