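"""Coarse-grained two-state simulator with a targeted-MD restraint.

The engine is a vacuum dual-basin structure-based ("Gō-like") model: one
bead per residue at the Cα position, bonded terms holding the chain
together, per-basin native-contact wells that stabilise each of the two
reference conformations, and a soft-core repulsion between non-native
pairs.  The two single-basin surfaces are blended with a log-sum-exp
soft minimum,

    V = -(1/β_mix) ln[ exp(-β_mix V_open) + exp(-β_mix V_closed) ],

so both references are local minima of the same potential and a
continuous transition path exists between them.

On top of that surface the module provides:

* staged energy minimization (steepest descent with backtracking, with
  harmonic positional restraints relaxed stage by stage, e.g.
  100 → 75 → 50 → 25 → 0 kcal/(mol·Å²));
* thermostatted Langevin (BAOAB) dynamics with a linear heating ramp,
  equilibration and production phases — the conventional-MD (CMD) analog;
* targeted MD (TMD): the per-atom harmonic restraint

      E_TMD = (k N / 2) [RMSD(t) - RMSD0(t)]²

  on the best-fit mass-weighted RMSD to a target structure, with the
  prescribed RMSD0(t) decaying linearly from the initial RMSD to zero,
  which steers the system from one conformation to the other.

Units: length Å, energy kcal/mol, mass Da, time ps.  Temperature coupling
τ maps to Langevin friction γ = 1/τ.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose, rmsd_gradient
from .structure_io import Structure, Trajectory

__all__ = [
    "KB",
    "ACCEL",
    "DualBasinParams",
    "DualBasinModel",
    "TMDRestraint",
    "SimProtocol",
    "SimResult",
    "build_dual_basin",
    "tmd_energy",
    "minimize",
    "run_cmd",
    "run_tmd",
]

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872041
#: Force → acceleration conversion: 1 kcal/(mol·Å) = ACCEL Da·Å/ps².
ACCEL = 418.4


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualBasinParams:
    """Parameters of the coarse-grained dual-basin potential.

    bond_k : kcal/(mol·Å²)
        Stiffness of the chain bonds (i,i+1) and, when ``pseudo_bonds`` is
        set, of the (i,i+2) angle-like pseudo-bonds that carry local
        backbone geometry.
    contact_k : kcal/(mol·Å²)
        Stiffness of native-contact wells.  Each well is a harmonic in
        (r - r0) truncated flat at the contact cutoff and shifted so it
        reaches zero there — contacts have a finite depth
        contact_k·(cutoff - r0)² and detach smoothly, which is what lets
        a biased trajectory actually break the starting basin.
    contact_cutoff : Å
        Pairs (|i-j| ≥ 3) closer than this in a basin's reference belong
        to that basin's native-contact set; it is also the truncation
        radius of the well.
    excluded_radius : Å
        Soft-core diameter: non-native pairs closer than this feel a
        harmonic repulsion.
    repulsion_k : kcal/(mol·Å²)
    beta_mix : (kcal/mol)⁻¹
        Sharpness of the log-sum-exp basin mixing; larger values give a
        harder switch between basins.
    """

    bond_k: float = 100.0
    contact_k: float = 0.2
    contact_cutoff: float = 7.5
    excluded_radius: float = 4.0
    repulsion_k: float = 10.0
    beta_mix: float = 0.05
    pseudo_bonds: bool = True


@dataclass
class _Basin:
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_r0: np.ndarray
    bond_r0: np.ndarray
    rep_mask: np.ndarray      # (n, n) symmetric bool, non-native |i-j|>=3 pairs


@dataclass
class DualBasinModel:
    """Dual-basin potential over two index-matched reference structures."""

    n_atoms: int
    masses: np.ndarray
    bond_i: np.ndarray
    bond_j: np.ndarray
    open_basin: _Basin
    closed_basin: _Basin
    open_coords: np.ndarray
    closed_coords: np.ndarray
    params: DualBasinParams

    # -- energetics ------------------------------------------------------

    def _scatter_pairs(self, i, j, pair_f, forces):
        n = self.n_atoms
        for d in range(3):
            forces[:, d] -= np.bincount(i, weights=pair_f[:, d], minlength=n)
            forces[:, d] += np.bincount(j, weights=pair_f[:, d], minlength=n)

    def _basin_energy_forces(self, x, diff, dist, basin: _Basin):
        p = self.params
        forces = np.zeros_like(x)

        # bonds: full harmonic
        d = dist[self.bond_i, self.bond_j]
        dr = d - basin.bond_r0
        energy = float(p.bond_k * np.sum(dr ** 2))
        coef = 2.0 * p.bond_k * dr / d
        pair_f = coef[:, None] * diff[self.bond_i, self.bond_j]
        self._scatter_pairs(self.bond_i, self.bond_j, pair_f, forces)

        # native contacts: truncated, shifted harmonic wells
        if basin.contact_i.size:
            d = dist[basin.contact_i, basin.contact_j]
            active = d < p.contact_cutoff
            dr = d - basin.contact_r0
            depth = (p.contact_cutoff - basin.contact_r0) ** 2
            energy += float(p.contact_k * np.sum((dr ** 2 - depth)[active]))
            coef = np.where(active, 2.0 * p.contact_k * dr / d, 0.0)
            pair_f = coef[:, None] * diff[basin.contact_i, basin.contact_j]
            self._scatter_pairs(basin.contact_i, basin.contact_j, pair_f, forces)

        # soft-core repulsion between non-native pairs
        act = basin.rep_mask & (dist < p.excluded_radius)
        if act.any():
            d = np.where(act, dist, 1.0)
            overlap = np.where(act, p.excluded_radius - d, 0.0)
            energy += float(0.5 * p.repulsion_k * np.sum(overlap ** 2))
            coef = 2.0 * p.repulsion_k * overlap / d
            forces += np.einsum("ij,ijk->ik", coef, diff)

        return energy, forces

    def energy_forces(self, x: np.ndarray):
        """Total potential (kcal/mol) and forces (kcal/(mol·Å)) at ``x``."""
        x = np.asarray(x, dtype=float)
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)

        v_o, f_o = self._basin_energy_forces(x, diff, dist, self.open_basin)
        v_c, f_c = self._basin_energy_forces(x, diff, dist, self.closed_basin)

        b = self.params.beta_mix
        lo, lc = -b * v_o, -b * v_c
        m = max(lo, lc)
        zo, zc = np.exp(lo - m), np.exp(lc - m)
        z = zo + zc
        energy = -(m + np.log(z)) / b
        w_o = zo / z
        forces = w_o * f_o + (1.0 - w_o) * f_c
        return energy, forces

    def energy(self, x: np.ndarray) -> float:
        return self.energy_forces(x)[0]


def _make_basin(ref: np.ndarray, bond_i, bond_j, params: DualBasinParams) -> _Basin:
    n = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    ii, jj = np.triu_indices(n, k=3)
    native = dist[ii, jj] < params.contact_cutoff
    ci, cj = ii[native], jj[native]
    rep = np.zeros((n, n), dtype=bool)
    rep[ii[~native], jj[~native]] = True
    rep |= rep.T
    return _Basin(
        contact_i=ci,
        contact_j=cj,
        contact_r0=dist[ci, cj],
        bond_r0=dist[bond_i, bond_j],
        rep_mask=rep,
    )


def build_dual_basin(
    open_ref: Structure,
    closed_ref: Structure,
    params: DualBasinParams | None = None,
) -> DualBasinModel:
    """Build the dual-basin model from two index-matched conformers.

    Both references become local minima of the blended potential (up to
    the ln2/β_mix mixing offset).  Native-contact sets are taken per
    basin: pairs with |i-j| ≥ 3 within ``contact_cutoff`` in that basin's
    reference.
    """
    if params is None:
        params = DualBasinParams()
    if open_ref.n_atoms != closed_ref.n_atoms:
        raise ValueError(
            f"mismatched atom counts: open {open_ref.n_atoms} vs "
            f"closed {closed_ref.n_atoms}"
        )
    n = open_ref.n_atoms
    if n < 4:
        raise ValueError("need at least 4 beads")

    idx = np.arange(n)
    bond_i = [idx[:-1]]
    bond_j = [idx[1:]]
    if params.pseudo_bonds and n > 2:
        bond_i.append(idx[:-2])
        bond_j.append(idx[2:])
    bond_i = np.concatenate(bond_i)
    bond_j = np.concatenate(bond_j)

    for name, ref in (("open", open_ref.coords), ("closed", closed_ref.coords)):
        blen = np.linalg.norm(ref[idx[:-1]] - ref[idx[1:]], axis=1)
        if params.contact_cutoff <= blen.max():
            raise ValueError(
                f"contact cutoff {params.contact_cutoff} Å does not exceed the "
                f"longest {name}-state chain bond ({blen.max():.2f} Å)"
            )
    if params.contact_cutoff <= params.excluded_radius:
        raise ValueError("contact cutoff must exceed the excluded-volume radius")

    return DualBasinModel(
        n_atoms=n,
        masses=open_ref.masses,
        bond_i=bond_i,
        bond_j=bond_j,
        open_basin=_make_basin(open_ref.coords, bond_i, bond_j, params),
        closed_basin=_make_basin(closed_ref.coords, bond_i, bond_j, params),
        open_coords=open_ref.coords.copy(),
        closed_coords=closed_ref.coords.copy(),
        params=params,
    )


# ---------------------------------------------------------------------------
# Targeted-MD restraint
# ---------------------------------------------------------------------------

@dataclass
class TMDRestraint:
    """Harmonic restraint on the mass-weighted RMSD to a target.

        E_TMD = (k N / 2) [RMSD(t) - RMSD0(t)]²

    ``k`` is the per-atom force constant (kcal/(mol·Å²)), ``N`` the number
    of restrained atoms, and RMSD0(t) the prescribed target RMSD, linearly
    interpolated from ``rmsd0_start`` at ``t_start`` to ``rmsd0_end`` at
    ``t_end`` and held at ``rmsd0_end`` afterwards.
    """

    k: float
    target: Structure
    selection: np.ndarray | None = None   # atom indices; None = all
    rmsd0_start: float = 0.0
    rmsd0_end: float = 0.0
    t_start: float = 0.0
    t_end: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.t_end < self.t_start:
            raise ValueError("schedule end before start")
        if self.selection is not None:
            self.selection = np.asarray(self.selection, dtype=int)
            if self.selection.size < 3:
                raise ValueError("need at least 3 restrained atoms")

    def n_restrained(self, n_atoms: int) -> int:
        return n_atoms if self.selection is None else int(self.selection.size)

    def rmsd0(self, t: float) -> float:
        if t <= self.t_start:
            return self.rmsd0_start
        if t >= self.t_end or self.t_end == self.t_start:
            return self.rmsd0_end
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return self.rmsd0_start + frac * (self.rmsd0_end - self.rmsd0_start)


def tmd_energy(
    frame: np.ndarray,
    restraint: TMDRestraint,
    t: float,
    masses: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float, float]:
    """Targeted-MD energy and forces at time ``t``.

    Returns ``(energy, forces, rmsd, rmsd0)`` with forces on the full
    frame (zero outside the restrained selection).
    """
    frame = np.asarray(frame, dtype=float)
    target = restraint.target.coords
    if masses is None:
        masses = restraint.target.masses
    sel = restraint.selection
    if sel is None:
        sel = np.arange(frame.shape[0])
    if frame.shape[0] != target.shape[0]:
        raise ValueError("frame does not match the restraint target")
    n = sel.size
    rmsd, grad = rmsd_gradient(frame[sel], target[sel], masses[sel])
    rmsd0 = restraint.rmsd0(t)
    dev = rmsd - rmsd0
    energy = 0.5 * restraint.k * n * dev * dev
    forces = np.zeros_like(frame)
    forces[sel] = -restraint.k * n * dev * grad
    return energy, forces, rmsd, rmsd0


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize(
    model: DualBasinModel,
    start: Structure,
    stages: list[tuple[float, int]] | None = None,
    restraint_reference: Structure | None = None,
    gtol: float = 1e-6,
) -> Structure:
    """Staged steepest-descent minimization with backtracking line search.

    Each stage applies a harmonic positional restraint of the stated
    strength (kcal/(mol·Å²)) toward ``restraint_reference`` (default: the
    starting structure), relaxed stage by stage as in the standard
    restrained-minimization protocol (100 → 75 → 50 → 25, then an
    unrestrained final stage).
    """
    if stages is None:
        stages = [(100.0, 5000), (75.0, 5000), (50.0, 5000), (25.0, 5000),
                  (0.0, 10000)]
    if not stages:
        raise ValueError("stages must be non-empty")
    ref = (restraint_reference or start).coords
    x = start.coords.copy()

    e0 = model.energy(x)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at start (overlapping beads?)")

    def total(xc, strength):
        e, f = model.energy_forces(xc)
        if strength > 0:
            d = xc - ref
            e += strength * float(np.sum(d * d))
            f = f - 2.0 * strength * d
        return e, f

    for strength, max_steps in stages:
        e, f = total(x, strength)
        step = 1e-3
        for _ in range(int(max_steps)):
            gmax = np.abs(f).max()
            if gmax < gtol:
                break
            direction = f / np.linalg.norm(f)
            # backtracking Armijo line search
            for _ in range(40):
                x_new = x + step * direction
                e_new, f_new = total(x_new, strength)
                if e_new <= e - 1e-4 * step * np.linalg.norm(f):
                    break
                step *= 0.5
            else:
                break
            x, e, f = x_new, e_new, f_new
            step *= 1.5
    return start.with_coords(x)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

@dataclass
class SimProtocol:
    """Heating / equilibration / production protocol for Langevin dynamics.

    Times in ps, temperatures in K.  ``coupling`` is the temperature
    coupling time τ; the Langevin friction is γ = 1/τ.  ``dt`` defaults
    to 10 fs, appropriate for the coarse-grained bead model.
    """

    heat_t_start: float = 0.0
    heat_t_end: float = 300.0
    heat_duration: float = 1.2
    heat_restraint: float = 25.0
    equil_duration: float = 2.0
    prod_duration: float = 20.0
    temperature: float = 300.0
    dt: float = 0.01
    coupling: float = 0.2
    stride: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        for name in ("heat_duration", "equil_duration", "prod_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.heat_t_start, self.heat_t_end, self.temperature) < 0:
            raise ValueError("temperatures must be non-negative")

    @property
    def friction(self) -> float:
        return 0.0 if self.coupling <= 0 else 1.0 / self.coupling


@dataclass
class SimResult:
    """A finished run: the sampled trajectory plus the per-sample log.

    ``log`` columns: step, time_ps, T_K, V, E_TMD, RMSD, RMSD0 (RMSD
    columns populated only for targeted runs).
    """

    trajectory: Trajectory
    log: pd.DataFrame
    final: Structure

    def write_log(self, path) -> None:
        self.log.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _check_stability(model: DualBasinModel, dt: float) -> None:
    # stiffest mode: bond spring 2k; require omega*dt well below 2
    omega = np.sqrt(2.0 * model.params.bond_k * ACCEL / model.masses.min())
    if omega * dt > 0.8:
        raise ValueError(
            f"time step {dt} ps unstable for bond stiffness "
            f"{model.params.bond_k} (omega*dt = {omega * dt:.2f} > 0.8)"
        )


def _run_dynamics(
    model: DualBasinModel,
    start: Structure,
    protocol: SimProtocol,
    seed: int,
    restraint: TMDRestraint | None,
    tmd_in_production_only: bool = True,
) -> SimResult:
    _check_stability(model, protocol.dt)
    rng = np.random.default_rng(seed)
    n = model.n_atoms
    m = model.masses[:, None]
    dt = protocol.dt
    gamma = protocol.friction

    x = start.coords.copy()
    t_init = protocol.heat_t_start if protocol.heat_duration > 0 else protocol.temperature
    sigma_v = np.sqrt(KB * max(t_init, 1e-12) * ACCEL / m)
    v = rng.standard_normal((n, 3)) * sigma_v

    heat_ref = start.coords.copy()
    phases = [
        ("heat", protocol.heat_duration),
        ("equil", protocol.equil_duration),
        ("prod", protocol.prod_duration),
    ]
    prod_t0 = protocol.heat_duration + protocol.equil_duration

    def forces_at(xc, t_abs):
        e, f = model.energy_forces(xc)
        if not np.isfinite(e) or abs(e) > 1e10:
            raise RuntimeError(
                f"unstable integration: potential {e:.3g} kcal/mol at t = {t_abs:.3f} ps"
            )
        e_tmd = rmsd = rmsd0 = np.nan
        phase_is_prod = t_abs >= prod_t0 - 1e-12
        if restraint is not None and (phase_is_prod or not tmd_in_production_only):
            t_sched = t_abs - prod_t0 if tmd_in_production_only else t_abs
            et, ft, rmsd, rmsd0 = tmd_energy(xc, restraint, t_sched, model.masses)
            e_tmd = et
            f = f + ft
        return e, f, e_tmd, rmsd, rmsd0

    frames, times = [], []
    log_rows = []
    t_abs = 0.0
    step_count = 0
    e_pot, f, e_tmd, rmsd, rmsd0 = forces_at(x, t_abs)

    for phase, duration in phases:
        n_steps = int(round(duration / dt))
        for i in range(n_steps):
            if phase == "heat" and protocol.heat_duration > 0:
                frac = (i + 0.5) / n_steps
                t_set = protocol.heat_t_start + frac * (
                    protocol.heat_t_end - protocol.heat_t_start)
            else:
                t_set = protocol.temperature

            restraint_k = protocol.heat_restraint if phase == "heat" else 0.0
            a = f * ACCEL / m
            if restraint_k > 0:
                a = a - 2.0 * restraint_k * (x - heat_ref) * ACCEL / m

            # BAOAB
            v = v + 0.5 * dt * a
            x = x + 0.5 * dt * v
            if gamma > 0:
                c1 = np.exp(-gamma * dt)
                c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
                sigma_v = np.sqrt(KB * max(t_set, 0.0) * ACCEL / m)
                v = c1 * v + c2 * sigma_v * rng.standard_normal((n, 3))
            x = x + 0.5 * dt * v
            e_pot, f, e_tmd, rmsd, rmsd0 = forces_at(x, t_abs + dt)
            a = f * ACCEL / m
            if restraint_k > 0:
                a = a - 2.0 * restraint_k * (x - heat_ref) * ACCEL / m
            v = v + 0.5 * dt * a

            t_abs += dt
            step_count += 1
            if phase == "prod" and (i + 1) % protocol.stride == 0:
                ke = 0.5 * float(np.sum(model.masses[:, None] * v * v)) / ACCEL
                t_inst = 2.0 * ke / (3.0 * n * KB)
                frames.append(x.copy())
                times.append(t_abs)
                log_rows.append((step_count, t_abs, t_inst, e_pot, e_tmd, rmsd, rmsd0))

    if not frames:
        # no production window: report the final state as a single frame
        ke = 0.5 * float(np.sum(model.masses[:, None] * v * v)) / ACCEL
        t_inst = 2.0 * ke / (3.0 * n * KB)
        frames, times = [x.copy()], [max(t_abs, dt)]
        log_rows = [(step_count, times[0], t_inst, e_pot, e_tmd, rmsd, rmsd0)]

    traj = Trajectory(
        topology=start,
        frames=np.array(frames),
        times=np.array(times),
    )
    log = pd.DataFrame(
        log_rows,
        columns=["step", "time_ps", "T_K", "V", "E_TMD", "RMSD", "RMSD0"],
    )
    return SimResult(trajectory=traj, log=log, final=start.with_coords(x))


def run_cmd(
    model: DualBasinModel,
    start: Structure,
    protocol: SimProtocol,
    seed: int = 0,
) -> SimResult:
    """Conventional (unbiased) Langevin dynamics under the protocol.

    Heating ramps the thermostat set-point linearly with a positional
    restraint toward the start; equilibration and production run at the
    final temperature.  Identical seed and protocol give bit-identical
    trajectories.
    """
    return _run_dynamics(model, start, protocol, seed, restraint=None)


def run_tmd(
    model: DualBasinModel,
    start: Structure,
    target: Structure,
    k: float,
    protocol: SimProtocol,
    seed: int = 0,
    selection: np.ndarray | None = None,
) -> SimResult:
    """Targeted MD from ``start`` toward ``target``.

    The restraint applies to all beads by default (the coarse-grained
    "backbone").  RMSD0 starts at the actual initial best-fit RMSD — so
    the run begins unstrained — and decays linearly to zero across the
    production window; the log tracks (t, RMSD, RMSD0, E_TMD) per sample.
    """
    if start.n_atoms != target.n_atoms:
        raise ValueError("start and target must be index-matched")
    sel = np.arange(start.n_atoms) if selection is None else np.asarray(selection)
    rmsd_init = kabsch_superpose(
        start.coords[sel], target.coords[sel], start.masses[sel]
    ).rmsd
    restraint = TMDRestraint(
        k=k,
        target=target,
        selection=None if selection is None else sel,
        rmsd0_start=rmsd_init,
        rmsd0_end=0.0,
        t_start=0.0,
        t_end=protocol.prod_duration,
    )
    return _run_dynamics(model, start, protocol, seed, restraint=restraint)
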