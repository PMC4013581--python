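"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the RMSD oracle
minimizes over rotations numerically (quaternion sampling + local
refinement) instead of the closed-form SVD, and the volume oracle is
Monte-Carlo integration of the exact geometric region.
"""

import numpy as np
from scipy.optimize import minimize as sp_minimize
from scipy.spatial.transform import Rotation


def weighted_rmsd_after(rotation, x, y, w):
    moved = x @ rotation.T
    diff = moved - y
    return float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / w.sum()))


def quaternion_rmsd_oracle(mobile, reference, weights=None, n_samples=400,
                           seed=0):
    """Best-fit weighted RMSD by brute-force search over rotations.

    Random unit-quaternion sampling followed by Nelder–Mead refinement of
    the best candidates in rotation-vector coordinates.  Accurate to well
    below 1e-6 Å on small point sets.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    n = x.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    xc = x - (w[:, None] * x).sum(0) / w.sum()
    yc = y - (w[:, None] * y).sum(0) / w.sum()

    rng = np.random.default_rng(seed)
    quats = rng.standard_normal((n_samples, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats)
    vals = [weighted_rmsd_after(r.as_matrix(), xc, yc, w) for r in rots]
    order = np.argsort(vals)

    def objective(rotvec):
        return weighted_rmsd_after(
            Rotation.from_rotvec(rotvec).as_matrix(), xc, yc, w)

    best = np.inf
    for idx in order[:3]:
        res = sp_minimize(
            objective, rots[idx].as_rotvec(), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, float(res.fun))
    return best


def mc_cavity_volume(coords, atom_radius, probe_radius, inner_bound,
                     n_samples=1_500_000, seed=0):
    """Monte-Carlo volume of the enclosed probe-admissible region.

    Integrates {v : |v| < inner_bound, min_i |v - c_i| >= atom_radius +
    probe_radius} by uniform sampling in the bounding sphere.
    ``inner_bound`` must enclose the cavity while excluding outside
    solvent (for a hollow shell: anything between cavity and shell).
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-inner_bound, inner_bound, (n_samples, 3))
    pts = pts[np.linalg.norm(pts, axis=1) < inner_bound]
    dmin = np.full(len(pts), np.inf)
    for c in coords:
        np.minimum(dmin, np.linalg.norm(pts - c, axis=1), out=dmin)
    frac = float((dmin >= atom_radius + probe_radius).mean())
    return frac * 4.0 / 3.0 * np.pi * inner_bound ** 3


def dccm_reference(delta):
    """Direct evaluation of the cross-correlation formula by loops.

    ``delta``: (n_frames, n_sites, 3) displacement vectors already
    centered (mean removed).  Returns the (n_sites, n_sites) matrix.
    """
    F, n, _ = delta.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(float(delta[f, i] @ delta[f, j]) for f in range(F)) / F
            di = sum(float(delta[f, i] @ delta[f, i]) for f in range(F)) / F
            dj = sum(float(delta[f, j] @ delta[f, j]) for f in range(F)) / F
            out[i, j] = num / np.sqrt(di * dj)
    return out
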