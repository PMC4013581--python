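"""Rigid-body superposition and RMSD primitives.

Everything downstream — the targeted-MD restraint, per-frame RMSD series,
frame fitting before correlation analysis — reduces to the same three
operations: the Kabsch optimal superposition of two index-matched point
sets, the gradient of the best-fit RMSD with respect to the mobile
coordinates, and mass centers of atom selections.

RMSD here is mass-weighted by default,

    RMSD = sqrt( sum_i w_i |x_i - y_i|^2 / sum_i w_i ),

evaluated after the weight-optimal rigid superposition.  Uniform weighting
is available by passing ``weights=None`` with ``mass_weighted=False`` on the
high-level helpers or simply by passing unit weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "superposed_rmsd",
    "rmsd_gradient",
    "mass_center",
    "GRADIENT_EPS",
]

#: Below this RMSD (Å) the RMSD gradient is declared zero: RMSD is not
#: differentiable at 0 and the TMD schedule ends there, so forces clamp
#: instead of producing NaNs.
GRADIENT_EPS = 1e-6


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid superposition of a mobile onto a reference point set.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper rotation matrix (det = +1) applied to centered mobile
        coordinates.
    translation : (3,) ndarray
        Translation such that ``mobile @ rotation.T + translation``
        superposes the mobile set onto the reference.
    rmsd : float
        Weighted root-mean-square deviation (Å) after superposition.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid motion to an (n, 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _check_pair(mobile: np.ndarray, reference: np.ndarray, weights) -> tuple:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"mobile must be (n, 3), got {mobile.shape}")
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mobile.shape[0]} vs "
            f"reference {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError(f"weights must be ({n},), got {weights.shape}")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    return mobile, reference, weights


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Weight-optimal rigid superposition (Kabsch algorithm).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
        Index-matched coordinate sets, n >= 3.
    weights : (n,) array, optional
        Per-atom weights (masses for mass-weighted RMSD).  ``None`` means
        uniform.

    Returns
    -------
    Superposition
        Proper rotation + translation minimizing the weighted RMSD, and
        the minimized RMSD itself.

    Raises
    ------
    ValueError
        On shape mismatch, fewer than 3 points, non-positive weights, or a
        degenerate (rank < 2) point set for which the rotation is not
        determined.
    """
    mobile, reference, w = _check_pair(mobile, reference, weights)
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - mob_c
    y = reference - ref_c

    # Weighted covariance; SVD gives the optimal rotation with the
    # standard det<0 reflection correction.
    cov = x.T @ (w[:, None] * y)
    u, s, vt = np.linalg.svd(cov)
    if np.sum(s > s[0] * 1e-12 if s[0] > 0 else s > 0) < 2:
        raise ValueError("degenerate point set: rank < 2, rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T

    moved = x @ rotation.T
    diff = moved - y
    msd = float((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum)
    rmsd = float(np.sqrt(max(msd, 0.0)))
    translation = ref_c - mob_c @ rotation.T
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def superposed_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Best-fit weighted RMSD (Å) between two index-matched sets."""
    return kabsch_superpose(mobile, reference, weights).rmsd


def rmsd_gradient(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Gradient of the best-fit weighted RMSD w.r.t. mobile coordinates.

    At the superposition optimum the derivatives through the rotation and
    translation vanish, leaving

        g_i = w_i (x_i - yhat_i) / (RMSD * sum_j w_j)

    where ``yhat`` is the reference brought into the mobile frame by the
    inverse of the optimal superposition.  Doubling all weights leaves the
    gradient unchanged (w cancels through the sum and the RMSD).

    Returns
    -------
    (rmsd, gradient) : (float, (n, 3) ndarray)
        The best-fit RMSD and its gradient.  When RMSD < ``GRADIENT_EPS``
        the gradient is exactly zero (clamping contract — no NaN).
    """
    mobile, reference, w = _check_pair(mobile, reference, weights)
    sup = kabsch_superpose(mobile, reference, w)
    if sup.rmsd < GRADIENT_EPS:
        return sup.rmsd, np.zeros_like(mobile)
    # Bring the reference into the mobile frame: yhat = R^T (y - t).
    yhat = (reference - sup.translation) @ sup.rotation
    grad = (w[:, None] * (mobile - yhat)) / (sup.rmsd * w.sum())
    return sup.rmsd, grad


def mass_center(
    coords: np.ndarray,
    masses: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted centroid of a (sub)set of atoms.

    Parameters
    ----------
    coords : (n, 3) array
    masses : (n,) array of Da, all > 0
    selection : index array, optional
        Atom indices to include; ``None`` means all.

    Returns
    -------
    (3,) ndarray in Å.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise ValueError("empty selection")
        coords = coords[selection]
        masses = masses[selection]
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()
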