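"""Post-trajectory analysis suite.

The standard read-outs used to characterise a two-state conformational
transition:

* per-frame best-fit RMSD to a reference (:func:`rmsd_series`);
* the dynamical cross-correlation matrix (DCCM) of per-residue
  displacement vectors,

      C(i,j) = <Δr_i · Δr_j> / sqrt(<Δr_i²> <Δr_j²>),

  with Δr_i(t) = r_i(t) − <r_i> after optional RMS fitting of every frame
  onto the mean structure (:func:`compute_dccm`);
* hydrogen-bond occupancy — the percentage of frames in which a
  donor→acceptor pair satisfies the geometric criteria
  (:func:`hbond_occupancy`);
* hydrophobic contacts — minimum carbon–carbon distance per frame with
  the strict d < 4.5 Å criterion (:func:`hydrophobic_contacts`);
* mass-center distance series between named segments
  (:func:`segment_distance_series`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose, mass_center
from .structure_io import SegmentTable, Structure, Trajectory

__all__ = [
    "DCCM",
    "HBondCriteria",
    "HBondPair",
    "ContactRecord",
    "rmsd_series",
    "compute_dccm",
    "hbond_occupancy",
    "hydrophobic_contacts",
    "segment_distance_series",
]


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> pd.DataFrame:
    """Per-frame best-fit RMSD (Å) of the trajectory to a reference.

    Returns a DataFrame with columns ``time_ps`` and ``rmsd``.
    """
    sel = np.arange(reference.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    if traj.frames.shape[1] != reference.n_atoms:
        raise ValueError("trajectory and reference atom counts differ")
    w = reference.masses[sel] if mass_weighted else None
    ref = reference.coords[sel]
    vals = [kabsch_superpose(f[sel], ref, w).rmsd for f in traj.frames]
    return pd.DataFrame({"time_ps": traj.times, "rmsd": vals})


# ---------------------------------------------------------------------------
# DCCM
# ---------------------------------------------------------------------------

@dataclass
class DCCM:
    """Residue×residue cross-correlation matrix.

    ``matrix[i, j]`` is C(i,j) ∈ [−1, 1]; entries involving a
    zero-variance site are NaN and flagged False in ``defined`` (they are
    reported as undefined, never silently zero).  ``residues`` maps matrix
    rows to residue numbers of the analysed sites.
    """

    matrix: np.ndarray
    residues: np.ndarray
    n_frames: int
    fitted: bool
    defined: np.ndarray = field(default=None)  # (n, n) bool

    def __post_init__(self):
        if self.defined is None:
            self.defined = np.isfinite(self.matrix)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    def value(self, res_i: int, res_j: int) -> float:
        idx = {r: k for k, r in enumerate(self.residues)}
        return float(self.matrix[idx[res_i], idx[res_j]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residues, columns=self.residues)

    def write(self, path) -> None:
        """Dense whitespace-delimited matrix with residue header row/column."""
        with open(path, "w") as fh:
            fh.write("# fit=%s n_frames=%d\n" % (self.fitted, self.n_frames))
            fh.write("res " + " ".join(str(r) for r in self.residues) + "\n")
            for r, row in zip(self.residues, self.matrix):
                fh.write(str(r) + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def compute_dccm(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> DCCM:
    """Cross-correlation matrix of site displacement vectors.

    ``selection`` picks one site per residue (default: every atom — the
    coarse-grained case where each bead is a residue).  With ``fit=True``
    (the default, standard practice) every frame is first superposed onto
    the mean structure; the mean is then recomputed and the fit applied
    once more, removing rigid-body motion before Δr is measured.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sel = np.arange(traj.frames.shape[1]) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    coords = traj.frames[:, sel, :].astype(float)

    if fit:
        # mean → fit → recompute mean → fit (one iteration)
        for _ in range(2):
            mean = coords.mean(axis=0)
            coords = np.array(
                [kabsch_superpose(f, mean).transform(f) for f in coords]
            )
    mean = coords.mean(axis=0)
    delta = coords - mean                       # (F, n, 3)

    cov = np.einsum("fik,fjk->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance site(s): correlations involving "
            "them are undefined and reported as masked entries"
        )
    if zero.all():
        raise ValueError("all selected sites have zero variance")
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    matrix = cov / denom
    defined = ~(zero[:, None] | zero[None, :])
    matrix[~defined] = np.nan
    # exact unit diagonal for defined sites
    matrix[np.diag_indices_from(matrix)] = np.where(zero, np.nan, 1.0)

    residues = traj.topology.res_indices[sel]
    return DCCM(
        matrix=matrix,
        residues=residues,
        n_frames=traj.n_frames,
        fitted=fit,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Default: donor–acceptor heavy-atom distance ≤ 3.5 Å and
    donor–H···acceptor angle ≥ 120° — the common trajectory-analysis
    convention.  Both are configuration, so occupancy tables can be
    reproduced under any chosen criteria.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 120.0

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class HBondPair:
    """A donor→acceptor pair named by residue number and atom name."""

    donor_res: int
    donor_atom: str
    acceptor_res: int
    acceptor_atom: str

    def label(self) -> str:
        return (
            f"({self.donor_res}){self.donor_atom}-H···"
            f"{self.acceptor_atom}({self.acceptor_res})"
        )


_H_BOND_LENGTH = 1.25  # Å: a hydrogen within this distance of the donor is bonded


def _donor_hydrogens(top: Structure, frame0: np.ndarray, donor_idx: int) -> np.ndarray:
    h_idx = np.array(
        [i for i, a in enumerate(top.atoms) if a.element == "H"], dtype=int
    )
    if h_idx.size == 0:
        return h_idx
    d = np.linalg.norm(frame0[h_idx] - frame0[donor_idx], axis=1)
    return h_idx[d <= _H_BOND_LENGTH]


def hbond_occupancy(
    traj: Trajectory,
    pairs: list[HBondPair],
    criteria: HBondCriteria | None = None,
) -> pd.DataFrame:
    """Occupancy (%) of each hydrogen bond over the trajectory.

    A frame counts when the donor–acceptor distance and the
    donor–H···acceptor angle (at the hydrogen, the best over the donor's
    hydrogens) both satisfy the criteria.  Occupancies are rounded to one
    decimal.  Pairs whose donor has no attached hydrogen are skipped with
    a warning.
    """
    if criteria is None:
        criteria = HBondCriteria()
    top = traj.topology
    rows = []
    cos_cut = np.cos(np.radians(criteria.angle_cutoff))
    for pair in pairs:
        d_idx = top.find_atom(pair.donor_res, pair.donor_atom)
        a_idx = top.find_atom(pair.acceptor_res, pair.acceptor_atom)
        h_idx = _donor_hydrogens(top, traj.frames[0], d_idx)
        if h_idx.size == 0:
            warnings.warn(
                f"no hydrogen bonded to donor {pair.label()}; pair skipped"
            )
            continue
        d_xyz = traj.frames[:, d_idx, :]
        a_xyz = traj.frames[:, a_idx, :]
        dist_ok = np.linalg.norm(d_xyz - a_xyz, axis=1) <= criteria.distance_cutoff
        angle_ok = np.zeros(traj.n_frames, dtype=bool)
        for h in h_idx:
            h_xyz = traj.frames[:, h, :]
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
            angle_ok |= cosang <= cos_cut + 1e-12
        hits = int(np.sum(dist_ok & angle_ok))
        occ = round(100.0 * hits / traj.n_frames, 1)
        rows.append(
            (pair.donor_res, pair.donor_atom, pair.acceptor_res,
             pair.acceptor_atom, occ)
        )
    return pd.DataFrame(
        rows,
        columns=["donor_res", "donor_atom", "acceptor_res", "acceptor_atom",
                 "occupancy_pct"],
    )


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactRecord:
    """Minimum carbon–carbon distance series for one residue pair."""

    res_i: int
    res_j: int
    distances: np.ndarray    # per-frame min C–C distance, Å
    contact: np.ndarray      # distances < cutoff (strict)
    cutoff: float


def hydrophobic_contacts(
    traj: Trajectory | Structure,
    residue_pairs: list[tuple[int, int]],
    cutoff: float = 4.5,
) -> list[ContactRecord]:
    """Hydrophobic-contact detection at the strict d < cutoff criterion.

    For each residue pair, records the per-frame minimum distance between
    carbon atoms (coarse-grained beads count as carbons) and whether it is
    strictly below the 4.5 Å hydrophobic-contact cutoff.  Symmetric in the
    pair order.
    """
    if isinstance(traj, Structure):
        traj = Trajectory(
            topology=traj, frames=traj.coords[None, :, :], times=np.array([0.0])
        )
    top = traj.topology
    records = []
    for ri, rj in residue_pairs:
        ci = np.array(
            [i for i, a in enumerate(top.atoms)
             if a.res_index == ri and a.element == "C"], dtype=int)
        cj = np.array(
            [i for i, a in enumerate(top.atoms)
             if a.res_index == rj and a.element == "C"], dtype=int)
        if ci.size == 0 or cj.size == 0:
            raise ValueError(
                f"residue pair ({ri}, {rj}) has no carbon atoms on one side"
            )
        xi = traj.frames[:, ci, :]          # (F, a, 3)
        xj = traj.frames[:, cj, :]          # (F, b, 3)
        diff = xi[:, :, None, :] - xj[:, None, :, :]
        dmin = np.sqrt(np.einsum("fabk,fabk->fab", diff, diff)).min(axis=(1, 2))
        records.append(ContactRecord(
            res_i=ri, res_j=rj, distances=dmin,
            contact=dmin < cutoff, cutoff=cutoff,
        ))
    return records


# ---------------------------------------------------------------------------
# Segment mass-center distances
# ---------------------------------------------------------------------------

def segment_distance_series(
    traj: Trajectory,
    segments: SegmentTable,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Mass-center distance (Å) between segment pairs, per frame.

    Distances are internal coordinates — no superposition is applied, so
    the series is invariant under rigid motion of whole frames.  Columns
    are named ``"A–B"`` per requested pair, plus ``time_ps``.
    """
    top = traj.topology
    masses = top.masses
    out = {"time_ps": traj.times}
    for a, b in pairs:
        ia = top.atom_indices(segments.residues(a))
        ib = top.atom_indices(segments.residues(b))
        if ia.size == 0 or ib.size == 0:
            raise ValueError(f"segment pair ({a!r}, {b!r}) selects no atoms")
        ca = np.array([mass_center(f, masses, ia) for f in traj.frames])
        cb = np.array([mass_center(f, masses, ib) for f in traj.frames])
        out[f"{a}–{b}"] = np.linalg.norm(ca - cb, axis=1)
    return pd.DataFrame(out)
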