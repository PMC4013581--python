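"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here, deterministically
in a seed:

* :func:`make_two_state_toy` — a coarse-grained two-state protein: a
  solenoid "core" shared by both conformers, with a terminal segment
  (the β7/8 analog) that relocates across the core between the open and
  closed states, mimicking a sheet translocation.  Both states have exact
  3.8 Å bonds and are clash-free, and the open↔closed RMSD is large
  enough (≥ 6 Å by default) that driving between them is a nontrivial
  transition.
* :func:`make_correlated_trajectory` — displacement series with planted
  correlated / anticorrelated site blocks over independent noise, for
  validating cross-correlation analysis end to end.
* :func:`make_hbond_fixture` — a donor/H/acceptor triad whose geometry
  satisfies the default hydrogen-bond criteria in an exactly prescribed
  fraction of frames.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structure_io import Atom, Segment, SegmentTable, Structure, Trajectory
from .trajectory_analysis import HBondPair

__all__ = [
    "ToySystem",
    "make_two_state_toy",
    "make_correlated_trajectory",
    "make_hbond_fixture",
    "make_hollow_shell",
    "BOND_LENGTH",
]

#: Consecutive-bead spacing, Å (the Cα–Cα virtual bond length).
BOND_LENGTH = 3.8
#: Minimum clearance between nonbonded beads (|i−j| ≥ 2) in either state.
_CLEARANCE = 4.0
_BEAD_MASS = 110.0  # Da, average residue mass


def _bead(i: int) -> Atom:
    return Atom(name="CA", element="C", res_index=i + 1, res_name="GLY",
                chain="A", mass=_BEAD_MASS)


def _bead_structure(coords: np.ndarray, title: str) -> Structure:
    return Structure(
        atoms=[_bead(i) for i in range(coords.shape[0])],
        coords=coords,
        title=title,
    )


@dataclass
class ToySystem:
    """A generated two-state toy protein with its segment annotation."""

    open: Structure
    closed: Structure
    segments: SegmentTable
    seed: int
    n_residues: int
    n_tail: int
    rmsd: float        # best-fit mass-weighted RMSD open↔closed


def _chord_walk(path: np.ndarray, start: np.ndarray, n_points: int,
                spacing: float) -> np.ndarray:
    """Points at exact Euclidean ``spacing`` steps along a dense polyline."""
    out = []
    cur = start.astype(float)
    k = 0
    for _ in range(n_points):
        while k < len(path) and np.linalg.norm(path[k] - cur) < spacing:
            k += 1
        if k >= len(path):
            raise ValueError("path too short for requested points")
        # bisect between path[k-1] (inside sphere) and path[k] (outside)
        lo_pt = path[k - 1] if k > 0 else cur
        hi_pt = path[k]
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            p = lo_pt + mid * (hi_pt - lo_pt)
            if np.linalg.norm(p - cur) < spacing:
                lo = mid
            else:
                hi = mid
        cur = lo_pt + hi * (hi_pt - lo_pt)
        out.append(cur.copy())
    return np.array(out)


def _toy_segments(n: int, n_tail: int) -> SegmentTable:
    """Toy analogs of the named structural elements, over 1-based beads.

    The core (everything before the relocating tail) is cut proportionally
    into β1 / αA / β5-αC loop / β6/4/5 / αC analogs; cuts are forced to
    advance by at least one residue so every segment is non-empty for any
    core of ≥ 6 residues.
    """
    core = n - n_tail
    cuts = []
    prev = 0
    for frac in (0.08, 0.30, 0.42, 0.72, 0.92):
        cut = max(prev + 1, round(frac * core))
        cuts.append(cut)
        prev = cut
    b1_end, aa_end, loop_end, sheet_end, ac_end = cuts
    segs = [
        Segment("β1", "strand", ((1, b1_end),)),
        Segment("αA", "helix", ((b1_end + 1, aa_end),)),
        Segment("β5-αC loop", "loop", ((aa_end + 1, loop_end),)),
        Segment("β6/4/5", "sheet-group", ((loop_end + 1, sheet_end),)),
        Segment("αC", "helix", ((sheet_end + 1, min(ac_end, core)),)),
    ]
    if ac_end < core:
        segs.append(Segment("linker", "loop", ((ac_end + 1, core),)))
    segs.append(Segment("β7/8", "sheet-group", ((core + 1, n),)))
    return SegmentTable(segs)


def make_two_state_toy(
    n_residues: int = 60,
    seed: int = 0,
    min_rmsd: float = 6.0,
) -> ToySystem:
    """Generate the packaged two-state toy protein.

    The open conformer places all beads on a solenoid (3.8 Å chords,
    ≥ 4.5 Å between turns).  The closed conformer keeps the core and
    relocates the terminal β7/8-analog segment along a smooth outward,
    around-the-core, downward path, re-spaced to exact 3.8 Å bonds.
    The seed fixes the global azimuthal phase, so coordinates are
    deterministic in the seed while bond lengths stay exact.

    Raises ``ValueError`` when ``n_residues`` is too small to form the
    designated segments, or if the construction violates its own
    clearance / separation invariants.
    """
    n = int(n_residues)
    if n < 20:
        raise ValueError("need at least 20 residues to form the toy segments")
    rng = np.random.default_rng(seed)
    phi0 = float(rng.uniform(0.0, 2.0 * np.pi))

    n_tail = max(8, round(n / 5))

    # --- open state: solenoid with exact 3.8 Å chords -------------------
    theta = 2.0 * np.pi / 9.0            # 9 beads per turn
    rise_per_turn = 4.6
    c = rise_per_turn / 9.0
    radius = np.sqrt((BOND_LENGTH ** 2 - c ** 2) / (2.0 * (1.0 - np.cos(theta))))
    i = np.arange(n)
    open_xyz = np.stack([
        radius * np.cos(phi0 + i * theta),
        radius * np.sin(phi0 + i * theta),
        c * i,
    ], axis=1)

    # --- closed state: core fixed, tail relocated -----------------------
    jc = n - n_tail - 1                  # last core bead (0-based)
    p0 = open_xyz[jc]
    phi_jc = phi0 + jc * theta
    r_out = radius + 4.8

    # dense curve: radial break-out (with a slight rise to clear the turn
    # below), then a descending wrap around the outside of the core
    t = np.linspace(0.0, 1.0, 400)[1:]
    seg_a = np.stack([
        (radius + t * (r_out - radius)) * np.cos(phi_jc + 0.25 * t),
        (radius + t * (r_out - radius)) * np.sin(phi_jc + 0.25 * t),
        p0[2] + 0.5 * t,
    ], axis=1)
    arc_total = n_tail * BOND_LENGTH + 6.0
    arc_b = arc_total - 4.9
    dphi = 0.73 * arc_b / r_out
    drop = 0.68 * arc_b
    t = np.linspace(0.0, 1.0, 4000)[1:]
    seg_b = np.stack([
        r_out * np.cos(phi_jc + 0.25 + dphi * t),
        r_out * np.sin(phi_jc + 0.25 + dphi * t),
        seg_a[-1, 2] - drop * t,
    ], axis=1)
    path = np.vstack([seg_a, seg_b])
    tail = _chord_walk(path, p0, n_tail, BOND_LENGTH)

    closed_xyz = open_xyz.copy()
    closed_xyz[jc + 1:] = tail

    # --- invariants ------------------------------------------------------
    for name, xyz in (("open", open_xyz), ("closed", closed_xyz)):
        bonds = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        if np.any(np.abs(bonds - BOND_LENGTH) > 0.01):
            raise ValueError(f"{name} state bond lengths out of tolerance")
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        ii, jj = np.triu_indices(n, k=2)
        if d[ii, jj].min() < _CLEARANCE:
            raise ValueError(
                f"{name} state clash: min nonbonded distance "
                f"{d[ii, jj].min():.2f} Å < {_CLEARANCE} Å"
            )

    open_s = _bead_structure(open_xyz, "toy two-state protein, open")
    closed_s = _bead_structure(closed_xyz, "toy two-state protein, closed")
    rmsd = kabsch_superpose(open_xyz, closed_xyz, open_s.masses).rmsd
    if rmsd < min_rmsd:
        raise ValueError(
            f"open↔closed RMSD {rmsd:.2f} Å below the required {min_rmsd} Å"
        )

    return ToySystem(
        open=open_s,
        closed=closed_s,
        segments=_toy_segments(n, n_tail),
        seed=seed,
        n_residues=n,
        n_tail=n_tail,
        rmsd=rmsd,
    )


def make_correlated_trajectory(
    n_sites: int,
    n_frames: int,
    blocks: list[tuple[set, set, int]] | None = None,
    noise_sigma: float = 0.3,
    amplitude: float = 1.2,
    seed: int = 0,
) -> Trajectory:
    """Trajectory with planted correlated / anticorrelated site blocks.

    Each block is ``(sites_a, sites_b, sign)`` with 1-based site numbers:
    all listed sites share one latent scalar motion along one random unit
    direction, the ``sites_b`` group multiplied by ``sign`` (+1 coupled,
    −1 anti-coupled).  Independent Gaussian noise (``noise_sigma`` per
    coordinate) is added everywhere.  At the defaults the expected
    within-block |C| is amplitude²/(amplitude² + 3σ²) ≈ 0.84 and the
    background |C| is 0 in expectation.

    Sites may appear in at most one block; overlap raises ``ValueError``.
    """
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    blocks = blocks or []
    seen: set[int] = set()
    for sa, sb, sign in blocks:
        if sign not in (-1, 1):
            raise ValueError("block sign must be +1 or -1")
        for s in set(sa) | set(sb):
            if s in seen:
                raise ValueError(f"site {s} appears in more than one block")
            if not 1 <= s <= n_sites:
                raise ValueError(f"site {s} outside 1..{n_sites}")
            seen.add(s)

    rng = np.random.default_rng(seed)
    base = np.zeros((n_sites, 3))
    base[:, 0] = 10.0 * np.arange(n_sites)

    disp = rng.normal(0.0, noise_sigma, size=(n_frames, n_sites, 3))
    for sa, sb, sign in blocks:
        e = rng.standard_normal(3)
        e /= np.linalg.norm(e)
        latent = rng.standard_normal(n_frames)
        for s in sa:
            disp[:, s - 1, :] += amplitude * latent[:, None] * e
        for s in sb:
            disp[:, s - 1, :] += sign * amplitude * latent[:, None] * e

    frames = base[None, :, :] + disp
    top = _bead_structure(frames[0], "planted-correlation fixture")
    return Trajectory(topology=top, frames=frames,
                      times=np.arange(n_frames, dtype=float))


def make_hollow_shell(
    n_atoms: int = 200,
    radius: float = 8.0,
    element: str = "C",
) -> Structure:
    """Spherical shell of atoms fully enclosing a hollow interior.

    Atoms are placed on a Fibonacci lattice — near-uniform coverage of the
    sphere, deterministic, no seed needed.  At the 200-atom default the
    inter-atom gaps are small enough that the enclosed probe-admissible
    volume for a 1.4 Å probe is within a few percent of the smooth-shell
    closed form (4/3)π(radius − r_atom − r_probe)³; sparser shells have a
    genuinely larger cavity because the probe-excluded envelope bulges
    outward between atoms.
    """
    if n_atoms < 20:
        raise ValueError("too few atoms to enclose a hollow")
    i = np.arange(n_atoms)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_atoms
    rho = np.sqrt(1.0 - z * z)
    xyz = radius * np.stack(
        [rho * np.cos(golden * i), rho * np.sin(golden * i), z], axis=1
    )
    atoms = [
        Atom(name=element, element=element, res_index=k + 1, res_name="SPH",
             chain="A", mass=12.011)
        for k in range(n_atoms)
    ]
    return Structure(atoms=atoms, coords=xyz,
                     title=f"hollow shell fixture, n={n_atoms} R={radius}")


def make_hbond_fixture(
    occupancy_target: float,
    n_frames: int = 1000,
    seed: int = 0,
) -> tuple[Trajectory, HBondPair, float]:
    """Trajectory whose H-bond occupancy is exact by construction.

    A donor N with its hydrogen faces an acceptor O that sits at ideal
    hydrogen-bond geometry (N···O 2.9 Å, N–H···O 180°) in exactly
    ``round(occupancy_target · n_frames / 100)`` frames and far away
    (7 Å) in the rest; which frames satisfy it is a seed-determined
    permutation.  Returns (trajectory, pair, exact occupancy %).
    """
    if not 0.0 <= occupancy_target <= 100.0:
        raise ValueError("occupancy target must be in [0, 100]")
    n_good = int(round(occupancy_target * n_frames / 100.0))
    rng = np.random.default_rng(seed)
    good = np.zeros(n_frames, dtype=bool)
    good[rng.permutation(n_frames)[:n_good]] = True

    atoms = [
        Atom(name="N", element="N", res_index=1, res_name="GLY", chain="A",
             mass=14.007),
        Atom(name="H", element="H", res_index=1, res_name="GLY", chain="A",
             mass=1.008),
        Atom(name="O", element="O", res_index=2, res_name="GLY", chain="A",
             mass=15.999),
    ]
    frames = np.zeros((n_frames, 3, 3))
    frames[:, 1, 0] = 1.0                          # H at (1, 0, 0)
    frames[:, 2, 0] = np.where(good, 2.9, 7.0)     # O in or out of geometry
    top = Structure(atoms=atoms, coords=frames[0], title="H-bond fixture")
    traj = Trajectory(topology=top, frames=frames,
                      times=np.arange(n_frames, dtype=float))
    pair = HBondPair(donor_res=1, donor_atom="N", acceptor_res=2,
                     acceptor_atom="O")
    return traj, pair, round(100.0 * n_good / n_frames, 1)
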