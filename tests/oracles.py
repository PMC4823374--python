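"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they are used to check: energies
are minimized by exhaustive enumeration, the constrained smoothing QP is
solved by a bound-constrained least-squares solver, and derivative
filters are realized as dense convolutions with explicitly sampled
kernels.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import lsq_linear
from scipy.signal import convolve2d


@lru_cache(maxsize=16)
def _all_labelings(n_voxels: int, n_labels: int) -> np.ndarray:
    """(L**n, n) array of every labeling of n voxels."""
    total = n_labels**n_voxels
    if total > 2**19:
        raise ValueError(f"enumeration of {total} labelings is too large")
    out = np.empty((total, n_voxels), dtype=np.int64)
    idx = np.arange(total)
    for v in range(n_voxels - 1, -1, -1):
        out[:, v] = idx % n_labels
        idx //= n_labels
    return out


def grid_edges(shape):
    """6-neighborhood edge lists: ((i, j) in-plane, (i, j) across-slice)."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    xy, z = [], []
    for axis, bucket in ((0, xy), (1, xy), (2, z)):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        bucket.append((idx[tuple(lo)].ravel(), idx[tuple(hi)].ravel()))
    join = lambda b: (
        np.concatenate([p[0] for p in b]),
        np.concatenate([p[1] for p in b]),
    )
    return join(xy), z[0]


def enumerate_min_energy(energy):
    """Global minimum of a small CRF energy by exhaustive enumeration."""
    shape = energy.shape
    n = int(np.prod(shape))
    labelings = _all_labelings(n, energy.n_labels)
    unary = energy.unary.reshape(n, energy.n_labels)
    e = unary[np.arange(n)[None, :], labelings].sum(axis=1)
    d = energy.dist_surrogate
    (xi, xj), (zi, zj) = grid_edges(shape)
    e += energy.theta_xy * d[labelings[:, xi], labelings[:, xj]].sum(axis=1)
    e += energy.theta_z * d[labelings[:, zi], labelings[:, zj]].sum(axis=1)
    k = int(np.argmin(e))
    best = np.asarray(energy.label_ids)[labelings[k]].reshape(shape)
    return float(e[k]), best


def qp_reference_objective(constraints) -> float:
    """Bound-constrained least-squares solution of the smoothing QP."""
    from vemseg.smoothing import _second_difference_operator, constraint_bounds

    a_op = _second_difference_operator(constraints.shape, constraints.rho)
    lb, ub = constraint_bounds(constraints)
    res = lsq_linear(a_op, np.zeros(a_op.shape[0]), bounds=(lb, ub),
                     tol=1e-12, max_iter=2000)
    return float(2.0 * res.cost)  # lsq_linear cost is 0.5 * ||A f||^2


def sampled_sxy_kernel(sigma: float) -> np.ndarray:
    """Dense sigma^2 * d^2 G / dx dy kernel: sampled, truncated at 4 sigma,
    sum-normalized and ramp-calibrated (unit response to a unit slope)."""
    r = int(np.ceil(4.0 * sigma))
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    dg = -(x / sigma**2) * g / g.sum()
    dg /= -np.sum(x * dg)  # exact unit-ramp response
    kx = sigma * dg
    return np.outer(kx, kx)  # separable: (sigma dG/dx) x (sigma dG/dy)


def dense_sxy_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Brute-force convolution oracle for the mixed second derivative.

    Only the interior (margin >= kernel radius) is comparable to the
    package's filtering, which uses mirror boundaries.
    """
    kernel = sampled_sxy_kernel(sigma)
    return convolve2d(image, kernel[::-1, ::-1], mode="same", boundary="symm")
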