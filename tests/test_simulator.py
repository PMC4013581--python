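import numpy as np
import pytest

from tmdpath.geometry import kabsch_superpose
from tmdpath.simulator import (
    ACCEL, KB, DualBasinParams, SimProtocol, TMDRestraint, build_dual_basin,
    minimize, run_cmd, run_tmd, tmd_energy,
)
from tmdpath.structure_io import Atom, Structure
from tmdpath.synthetic_data import make_two_state_toy


def total_energy(model, log):
    """Potential + kinetic reconstructed from the instantaneous temperature."""
    n = model.n_atoms
    return log["V"] + 1.5 * n * KB * log["T_K"]


class TestDualBasin:
    def test_references_are_minima_up_to_mixing(self, toy, model):
        beta = model.params.beta_mix
        for ref, basin in ((toy.open, "open"), (toy.closed, "closed")):
            e_total, forces = model.energy_forces(ref.coords)
            diff = ref.coords[:, None, :] - ref.coords[None, :, :]
            dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            np.fill_diagonal(dist, np.inf)
            e_single, _ = model._basin_energy_forces(
                ref.coords, diff, dist,
                model.open_basin if basin == "open" else model.closed_basin)
            assert e_total <= e_single + 1e-9
            assert e_total >= e_single - np.log(2.0) / beta - 1e-9
            assert np.abs(np.linalg.norm(forces, axis=1)).max() <= 1e-3

    def test_forces_match_finite_differences(self, toy, model, rng):
        x = toy.open.coords + rng.normal(0, 0.2, toy.open.coords.shape)
        _, forces = model.energy_forces(x)
        h = 1e-6
        for idx in [(0, 0), (10, 1), (30, 2), (47, 0), (59, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = -(model.energy(xp) - model.energy(xm)) / (2 * h)
            assert abs(fd - forces[idx]) <= 1e-4

    def test_mismatched_atom_counts(self, toy):
        smaller = Structure(atoms=toy.open.atoms[:-1],
                            coords=toy.open.coords[:-1])
        with pytest.raises(ValueError, match="mismatched"):
            build_dual_basin(smaller, toy.closed)

    def test_cutoff_validation(self, toy):
        with pytest.raises(ValueError, match="cutoff"):
            build_dual_basin(toy.open, toy.closed,
                             DualBasinParams(contact_cutoff=3.0))


class TestTMDEnergy:
    def make_pair(self, n, rng):
        atoms = [Atom("CA", "C", i + 1, "GLY", "A", 110.0) for i in range(n)]
        coords = rng.standard_normal((n, 3)) * 8.0
        return Structure(atoms=atoms, coords=coords)

    def test_on_schedule_is_zero(self, toy):
        restraint = TMDRestraint(k=0.5, target=toy.closed,
                                 rmsd0_start=toy.rmsd, rmsd0_end=0.0,
                                 t_start=0.0, t_end=10.0)
        e, f, rmsd, rmsd0 = tmd_energy(toy.open.coords, restraint, 0.0,
                                       toy.open.masses)
        assert rmsd0 == pytest.approx(toy.rmsd)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() <= 1e-9

    def test_direct_evaluation(self, rng):
        """E = ½ k N (RMSD − RMSD0)²: k=0.5, N=100, deviation 2 Å → 100."""
        target = self.make_pair(100, rng)
        restraint = TMDRestraint(k=0.5, target=target,
                                 rmsd0_start=0.0, rmsd0_end=0.0)
        # uniform displacement never changes the best-fit RMSD, so build a
        # frame at a known RMSD by direct measurement instead
        frame = target.coords + rng.normal(0, 1.0, (100, 3))
        rmsd = kabsch_superpose(frame, target.coords, target.masses).rmsd
        e, _, _, _ = tmd_energy(frame, restraint, 0.0, target.masses)
        assert e == pytest.approx(0.5 * 0.5 * 100 * rmsd ** 2, rel=1e-9)
        # the printed example: deviation exactly 2 Å
        assert 0.5 * 0.5 * 100 * 2.0 ** 2 == pytest.approx(100.0)

    def test_energy_linear_in_restrained_count(self, rng):
        """Doubling N at identical geometry doubles E.

        Superimposed duplicate copies leave the best-fit RMSD unchanged
        (same covariance, doubled weights) while N doubles.
        """
        target1 = self.make_pair(50, rng)
        frame1 = target1.coords + rng.normal(0, 0.8, (50, 3))
        atoms2 = [Atom("CA", "C", i + 1, "GLY", "A", 110.0) for i in range(100)]
        target2 = Structure(atoms=atoms2,
                            coords=np.vstack([target1.coords,
                                              target1.coords]))
        frame2 = np.vstack([frame1, frame1])
        r1 = TMDRestraint(k=0.5, target=target1)
        r2 = TMDRestraint(k=0.5, target=target2)
        e1 = tmd_energy(frame1, r1, 0.0, target1.masses)[0]
        e2 = tmd_energy(frame2, r2, 0.0, target2.masses)[0]
        assert e2 == pytest.approx(2.0 * e1, rel=1e-9)

    def test_schedule_interpolation_and_hold(self, toy):
        restraint = TMDRestraint(k=0.5, target=toy.closed,
                                 rmsd0_start=8.0, rmsd0_end=0.0,
                                 t_start=0.0, t_end=10.0)
        assert restraint.rmsd0(-1.0) == 8.0
        assert restraint.rmsd0(5.0) == pytest.approx(4.0)
        assert restraint.rmsd0(10.0) == 0.0
        assert restraint.rmsd0(25.0) == 0.0   # holds after the schedule

    def test_selection_mismatch(self, toy):
        restraint = TMDRestraint(k=0.5, target=toy.closed)
        with pytest.raises(ValueError, match="match"):
            tmd_energy(toy.open.coords[:-1], restraint, 0.0)


class TestMinimize:
    def test_fixed_point_at_basin_minimum(self, toy, model):
        out = minimize(model, toy.open, stages=[(0.0, 200)], gtol=1e-6)
        assert np.abs(out.coords - toy.open.coords).max() <= 1e-4

    def test_energy_decreases_per_stage(self, toy, model, rng):
        start = toy.open.with_coords(
            toy.open.coords + rng.normal(0, 0.3, toy.open.coords.shape))
        energies = [model.energy(start.coords)]
        current = start
        for strength in (100.0, 75.0, 50.0, 25.0, 0.0):
            current = minimize(model, current, stages=[(strength, 150)],
                               restraint_reference=toy.open, gtol=1e-5)
            energies.append(model.energy(current.coords))
        assert energies[-1] < energies[0]
        assert all(b <= a + 1e-6 for a, b in zip(energies[:-1], energies[1:]))

    def test_stiff_restraint_pins_to_reference(self, toy, model, rng):
        start = toy.open.with_coords(
            toy.open.coords + rng.normal(0, 0.3, toy.open.coords.shape))
        out = minimize(model, start, stages=[(1e6, 4000)],
                       restraint_reference=toy.open, gtol=1e-8)
        assert np.abs(out.coords - toy.open.coords).max() <= 0.01

    def test_empty_stages_rejected(self, toy, model):
        with pytest.raises(ValueError, match="non-empty"):
            minimize(model, toy.open, stages=[])


class TestDynamics:
    def test_determinism(self, toy, model):
        protocol = SimProtocol(heat_duration=0.5, equil_duration=0.5,
                               prod_duration=2.0, stride=10)
        a = run_cmd(model, toy.open, protocol, seed=11)
        b = run_cmd(model, toy.open, protocol, seed=11)
        assert np.array_equal(a.trajectory.frames, b.trajectory.frames)
        c = run_cmd(model, toy.open, protocol, seed=12)
        assert not np.array_equal(a.trajectory.frames, c.trajectory.frames)

    def test_energy_conservation_without_thermostat(self, toy, model):
        """γ = 0 reduces BAOAB to velocity Verlet; E is conserved."""
        protocol = SimProtocol(
            heat_duration=0.0, equil_duration=0.0, prod_duration=20.0,
            dt=0.002, coupling=0.0, temperature=300.0, stride=50,
        )
        res = run_cmd(model, toy.open, protocol, seed=5)
        e = total_energy(model, res.log)
        drift = np.abs(e - e.iloc[0]).max() / abs(e.iloc[0])
        assert drift <= 1e-3

    def test_zero_temperature_stays_at_minimum(self, toy, model):
        protocol = SimProtocol(heat_duration=0.0, equil_duration=0.0,
                               prod_duration=5.0, temperature=0.0, stride=10)
        res = run_cmd(model, toy.open, protocol, seed=0)
        drift = np.abs(res.final.coords - toy.open.coords).max()
        assert drift <= 0.05

    def test_production_temperature(self, toy, model):
        protocol = SimProtocol(heat_duration=1.0, equil_duration=2.0,
                               prod_duration=20.0, temperature=300.0,
                               stride=10)
        res = run_cmd(model, toy.open, protocol, seed=2)
        assert res.log["T_K"].mean() == pytest.approx(300.0, rel=0.05)

    def test_unstable_time_step_rejected(self, toy, model):
        protocol = SimProtocol(prod_duration=1.0, dt=0.5)
        with pytest.raises(ValueError, match="unstable"):
            run_cmd(model, toy.open, protocol, seed=0)


class TestTargetedRuns:
    def test_stiff_bias_reaches_target(self, toy, model):
        protocol = SimProtocol(heat_duration=0.5, equil_duration=0.5,
                               prod_duration=60.0, stride=25)
        res = run_tmd(model, toy.open, toy.closed, k=10.0,
                      protocol=protocol, seed=1)
        final = kabsch_superpose(res.final.coords, toy.closed.coords,
                                 toy.open.masses).rmsd
        assert final <= 0.5

    def test_schedule_tracking_band(self, tmd_default_runs):
        """|RMSD − RMSD0| stays inside the toy's operating band at k = 0.5."""
        for name in ("forward", "reverse"):
            res, _ = tmd_default_runs[name]
            lag = (res.log["RMSD"] - res.log["RMSD0"]).abs()
            assert lag.max() <= 1.5

    def test_log_tracks_schedule(self, tmd_default_runs):
        res, _ = tmd_default_runs["forward"]
        log = res.log
        assert {"time_ps", "RMSD", "RMSD0", "E_TMD"} <= set(log.columns)
        # RMSD0 decays linearly to zero across production
        assert log["RMSD0"].iloc[0] > 5.0
        assert log["RMSD0"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        assert (np.diff(log["RMSD0"]) <= 1e-9).all()

    def test_mismatched_start_target(self, toy, model):
        smaller = Structure(atoms=toy.open.atoms[:-1],
                            coords=toy.open.coords[:-1])
        protocol = SimProtocol(prod_duration=1.0)
        with pytest.raises(ValueError, match="index-matched"):
            run_tmd(model, smaller, toy.closed, k=0.5, protocol=protocol)
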