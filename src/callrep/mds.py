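"""Classical (Torgerson) multidimensional scaling.

Embeds a symmetric zero-diagonal distance matrix into Euclidean coordinates
by double-centering the squared distances and taking the top eigenvectors,
scaled by the square root of their eigenvalues.  Sign indeterminacy of each
axis is fixed by orienting it so that its largest-magnitude coordinate is
positive, making outputs reproducible across platforms.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mds_embed"]


def mds_embed(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical MDS coordinates, shape (n, dims).

    If fewer than ``dims`` eigenvalues are positive the deficient axes are
    zero-padded and a warning is emitted.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if n <= dims:
        raise ValueError(f"need more than dims={dims} points, got n={n}")

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    B = (B + B.T) / 2  # symmetrize against fp noise
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_pos = int(np.sum(evals > 1e-10))
    use = min(dims, n_pos)
    X = np.zeros((n, dims))
    if use > 0:
        X[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues for {dims} requested MDS axes; "
            "deficient axes zero-padded",
            stacklevel=2,
        )
    # deterministic sign: largest-|coordinate| entry of each axis positive
    for k in range(dims):
        col = X[:, k]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                X[:, k] = -col
    return X
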