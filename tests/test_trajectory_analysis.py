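import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmdpath.structure_io import Atom, Structure, Trajectory
from tmdpath.synthetic_data import (
    make_correlated_trajectory, make_hbond_fixture, make_two_state_toy,
)
from tmdpath.trajectory_analysis import (
    HBondCriteria, HBondPair, compute_dccm, hbond_occupancy,
    hydrophobic_contacts, rmsd_series, segment_distance_series,
)

from .oracles import dccm_reference


def bead_traj(frames, times=None, element="C"):
    n = frames.shape[1]
    atoms = [Atom("CA", element, i + 1, "GLY", "A", 110.0) for i in range(n)]
    top = Structure(atoms=atoms, coords=frames[0])
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    return Trajectory(topology=top, frames=frames, times=times)


class TestRMSDSeries:
    def test_identical_frames_are_zero(self, toy):
        frames = np.stack([toy.open.coords] * 4)
        traj = Trajectory(topology=toy.open, frames=frames,
                          times=np.arange(4.0))
        df = rmsd_series(traj, toy.open)
        assert np.abs(df["rmsd"]).max() <= 1e-9

    def test_rigid_copies_are_zero(self, toy):
        frames = []
        for f in range(4):
            rot = Rotation.random(
                random_state=np.random.RandomState(f)).as_matrix()
            frames.append(toy.open.coords @ rot.T + f)
        traj = Trajectory(topology=toy.open, frames=np.array(frames),
                          times=np.arange(4.0))
        assert np.abs(rmsd_series(traj, toy.open)["rmsd"]).max() <= 1e-9

    def test_matches_per_frame_oracle(self, toy, rng):
        from tmdpath.geometry import kabsch_superpose
        frames = toy.open.coords + np.cumsum(
            rng.normal(0, 0.2, (5, 60, 3)), axis=0)
        traj = Trajectory(topology=toy.open, frames=frames,
                          times=np.arange(5.0))
        df = rmsd_series(traj, toy.open)
        for i in range(5):
            expect = kabsch_superpose(frames[i], toy.open.coords,
                                      toy.open.masses).rmsd
            assert df["rmsd"][i] == pytest.approx(expect, abs=1e-12)


class TestDCCM:
    def test_perfect_correlation_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        latent = rng.standard_normal(30)
        base = np.zeros((3, 3))
        base[:, 0] = [0.0, 10.0, 20.0]
        frames = np.stack([base] * 30)
        frames[:, 0, 2] += latent
        frames[:, 1, 2] += latent           # co-moving with site 0
        frames[:, 2, 2] -= latent           # mirrored
        d = compute_dccm(bead_traj(frames), fit=False)
        assert d.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert d.matrix[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_three_site_four_frame_hand_evaluation(self):
        """Match the correlation formula evaluated by explicit loops."""
        frames = np.array([
            [[0.0, 0, 0], [10.0, 1, 0], [20.0, 0, 2]],
            [[1.0, 0, 1], [10.0, 0, 0], [20.0, 1, 0]],
            [[0.0, 1, 0], [11.0, 0, 1], [21.0, 0, 0]],
            [[1.0, 1, 1], [11.0, 1, 1], [19.0, 1, 2]],
        ])
        d = compute_dccm(bead_traj(frames), fit=False)
        delta = frames - frames.mean(axis=0)
        np.testing.assert_allclose(d.matrix, dccm_reference(delta),
                                   atol=1e-12)

    def test_unit_diagonal_and_symmetry(self, rng):
        frames = rng.normal(0, 1.0, (20, 6, 3))
        frames[:, :, 0] += 10.0 * np.arange(6)
        d = compute_dccm(bead_traj(frames), fit=False)
        np.testing.assert_allclose(np.diag(d.matrix), 1.0, atol=1e-12)
        np.testing.assert_allclose(d.matrix, d.matrix.T, atol=1e-12)
        assert np.nanmax(np.abs(d.matrix)) <= 1.0 + 1e-9

    def test_zero_variance_site_masked_not_propagated(self, rng):
        frames = rng.normal(0, 1.0, (20, 3, 3))
        frames[:, 1, :] = 5.0              # frozen site
        with pytest.warns(UserWarning, match="zero-variance"):
            d = compute_dccm(bead_traj(frames), fit=False)
        assert not d.defined[0, 1] and not d.defined[1, 1]
        assert np.isnan(d.matrix[0, 1])
        assert d.defined[0, 2]
        assert np.isfinite(d.matrix[0, 2])

    def test_single_frame_rejected(self, rng):
        frames = rng.normal(0, 1.0, (1, 3, 3))
        with pytest.raises(ValueError, match="2 frames"):
            compute_dccm(bead_traj(frames))

    def test_fit_adds_no_correlation_beyond_sampling_noise(self):
        """Rigid-motion removal leaves the noise DCCM unchanged.

        Frames differing only by rigid motions plus independent per-site
        noise: after fitting, the matrix must match the DCCM of the same
        noise without any rigid motion to within a small tolerance, and
        the mean |off-diagonal| must stay at the finite-sample level
        (~1/sqrt(3F)).
        """
        toy = make_two_state_toy(60, seed=0)
        rng = np.random.default_rng(42)
        F = 200
        noise = rng.normal(0, 0.3, (F, 60, 3))
        plain = toy.open.coords + noise
        rigid = np.empty_like(plain)
        for f in range(F):
            rot = Rotation.random(
                random_state=np.random.RandomState(f)).as_matrix()
            rigid[f] = plain[f] @ rot.T + rng.normal(0, 5.0, 3)
        d_plain = compute_dccm(bead_traj(plain), fit=False)
        d_rigid = compute_dccm(bead_traj(rigid), fit=True)
        assert np.abs(d_rigid.matrix - d_plain.matrix).max() <= 0.1
        off = d_rigid.matrix[~np.eye(60, dtype=bool)]
        assert np.abs(off).mean() <= 0.06


class TestHBondOccupancy:
    def test_constructed_half_occupancy(self):
        traj, pair, expected = make_hbond_fixture(50.0, n_frames=100, seed=3)
        df = hbond_occupancy(traj, [pair])
        assert df["occupancy_pct"][0] == expected == 50.0

    def test_never_and_always(self):
        for target in (0.0, 100.0):
            traj, pair, _ = make_hbond_fixture(target, n_frames=40, seed=0)
            df = hbond_occupancy(traj, [pair])
            assert df["occupancy_pct"][0] == target

    def test_frame_reordering_invariance(self):
        traj, pair, _ = make_hbond_fixture(37.0, n_frames=100, seed=5)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(topology=traj.topology,
                              frames=traj.frames[perm],
                              times=np.arange(traj.n_frames, dtype=float))
        a = hbond_occupancy(traj, [pair])["occupancy_pct"][0]
        b = hbond_occupancy(shuffled, [pair])["occupancy_pct"][0]
        assert a == b

    def test_missing_hydrogen_skipped_with_warning(self):
        traj, pair, _ = make_hbond_fixture(50.0, n_frames=10, seed=0)
        bad = HBondPair(donor_res=2, donor_atom="O",
                        acceptor_res=1, acceptor_atom="N")
        with pytest.warns(UserWarning, match="no hydrogen"):
            df = hbond_occupancy(traj, [bad])
        assert len(df) == 0

    def test_angle_criterion_rejects_bent_geometry(self):
        # donor-acceptor close but the hydrogen points away: angle ~0°
        atoms = [
            Atom("N", "N", 1, "GLY", "A", 14.007),
            Atom("H", "H", 1, "GLY", "A", 1.008),
            Atom("O", "O", 2, "GLY", "A", 15.999),
        ]
        frames = np.zeros((5, 3, 3))
        frames[:, 1, 0] = -1.0          # H on the far side of the donor
        frames[:, 2, 0] = 2.9
        top = Structure(atoms=atoms, coords=frames[0])
        traj = Trajectory(topology=top, frames=frames,
                          times=np.arange(5.0))
        pair = HBondPair(1, "N", 2, "O")
        df = hbond_occupancy(traj, [pair])
        assert df["occupancy_pct"][0] == 0.0

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(distance_cutoff=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=200.0)


class TestHydrophobicContacts:
    def two_carbon_structure(self, separation):
        atoms = [
            Atom("C1", "C", 1, "LEU", "A", 12.011),
            Atom("C1", "C", 2, "PHE", "A", 12.011),
        ]
        coords = np.array([[0.0, 0, 0], [separation, 0, 0]])
        return Structure(atoms=atoms, coords=coords)

    def test_strict_cutoff_boundary(self):
        """4.49 Å is a contact; exactly 4.50 Å is not (strict <)."""
        rec = hydrophobic_contacts(self.two_carbon_structure(4.49),
                                   [(1, 2)])[0]
        assert rec.contact[0]
        rec = hydrophobic_contacts(self.two_carbon_structure(4.50),
                                   [(1, 2)])[0]
        assert not rec.contact[0]

    def test_min_distance_matches_brute_force(self, rng):
        atoms, coords = [], []
        for res in range(1, 4):
            for k in range(4):
                atoms.append(Atom(f"C{k}", "C", res, "LEU", "A", 12.011))
                coords.append(rng.normal(res * 4.0, 1.0, 3))
        top = Structure(atoms=atoms, coords=np.array(coords))
        frames = top.coords + rng.normal(0, 0.3, (6, 12, 3))
        traj = Trajectory(topology=top, frames=frames,
                          times=np.arange(6.0))
        recs = hydrophobic_contacts(traj, [(1, 3)])
        for f in range(6):
            brute = min(
                np.linalg.norm(frames[f, i] - frames[f, j])
                for i in range(4) for j in range(8, 12)
            )
            assert recs[0].distances[f] == pytest.approx(brute, abs=1e-12)

    def test_symmetric_in_pair_order(self, toy):
        a = hydrophobic_contacts(toy.open, [(2, 59)])[0]
        b = hydrophobic_contacts(toy.open, [(59, 2)])[0]
        np.testing.assert_allclose(a.distances, b.distances)

    def test_no_carbon_error(self):
        atoms = [
            Atom("N", "N", 1, "GLY", "A", 14.007),
            Atom("C", "C", 2, "GLY", "A", 12.011),
        ]
        s = Structure(atoms=atoms, coords=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="no carbon"):
            hydrophobic_contacts(s, [(1, 2)])


class TestSegmentDistances:
    def test_constant_distance(self):
        from tmdpath.structure_io import Segment, SegmentTable
        atoms = [Atom("CA", "C", i + 1, "GLY", "A", 110.0) for i in range(2)]
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 7.0
        frames += np.arange(4)[:, None, None]      # rigid translation drift
        top = Structure(atoms=atoms, coords=frames[0])
        traj = Trajectory(topology=top, frames=frames, times=np.arange(4.0))
        table = SegmentTable([
            Segment("a", "strand", ((1, 1),)),
            Segment("b", "strand", ((2, 2),)),
        ])
        df = segment_distance_series(traj, table, [("a", "b")])
        np.testing.assert_allclose(df["a–b"], 7.0, atol=1e-12)

    def test_translation_invariance(self, toy, rng):
        frames = np.stack([toy.open.coords] * 3)
        shifted = frames + rng.normal(0, 20.0, (3, 1, 3))
        t1 = Trajectory(topology=toy.open, frames=frames,
                        times=np.arange(3.0))
        t2 = Trajectory(topology=toy.open, frames=shifted,
                        times=np.arange(3.0))
        pairs = [("β1", "αA"), ("β7/8", "αC")]
        df1 = segment_distance_series(t1, toy.segments, pairs)
        df2 = segment_distance_series(t2, toy.segments, pairs)
        for col in ("β1–αA", "β7/8–αC"):
            np.testing.assert_allclose(df1[col], df2[col], atol=1e-9)

    def test_tmd_run_trends_between_endpoint_values(self, toy,
                                                    tmd_default_runs):
        """The relocating segment's distance series moves from its open-state
        value toward its closed-state value along the transition."""
        res, _ = tmd_default_runs["forward"]
        pair = [("β7/8", "αC")]
        df = segment_distance_series(res.trajectory, toy.segments, pair)
        open_val = segment_distance_series(
            Trajectory(topology=toy.open,
                       frames=toy.open.coords[None], times=[1.0]),
            toy.segments, pair).iloc[0, 1]
        closed_val = segment_distance_series(
            Trajectory(topology=toy.closed,
                       frames=toy.closed.coords[None], times=[1.0]),
            toy.segments, pair).iloc[0, 1]
        series = df.iloc[:, 1]
        assert abs(series.iloc[0] - open_val) < 2.0
        assert abs(series.iloc[-1] - closed_val) < 2.0
        # overall drift in the direction of the endpoint difference; the
        # middle is allowed to be non-monotone (the tail travels around
        # the core, so its distance to αC dips before rising)
        from scipy.stats import spearmanr
        rho = spearmanr(df["time_ps"], series).statistic
        assert rho * (closed_val - open_val) > 0
        assert abs(rho) > 0.5

    def test_unknown_segment(self, toy):
        frames = toy.open.coords[None]
        traj = Trajectory(topology=toy.open, frames=frames, times=[1.0])
        with pytest.raises(KeyError):
            segment_distance_series(traj, toy.segments, [("β1", "nope")])
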