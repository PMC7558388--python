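"""Rigid-body geometry helpers shared by the conformer and matching code."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_superpose", "rigid_rmsd", "pairwise_distances"]


def kabsch_superpose(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rigid superposition of point set ``a`` onto ``b``.

    Returns ``(rotation, translation, rmsd)`` such that ``a @ rotation.T +
    translation`` best fits ``b``; the rotation is proper (determinant +1),
    so mirror images of chiral sets retain a positive residual.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique proper rotation")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (a - ca) @ rot.T + cb
    rmsd = float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))
    trans = cb - rot @ ca
    return rot, trans, rmsd


def rigid_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal proper rigid superposition (no atom reordering).

    Degenerate sizes are handled analytically: one point always superposes
    exactly; for two points the optimal fit leaves half the difference in
    separations at each end.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets must share shape; got {a.shape} vs {b.shape}")
    if a.shape[0] == 1:
        return 0.0
    if a.shape[0] == 2:
        return abs(np.linalg.norm(a[1] - a[0]) - np.linalg.norm(b[1] - b[0])) / 2.0
    return kabsch_superpose(a, b)[2]


def pairwise_distances(x: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix of a point set (n, 3)."""
    x = np.asarray(x, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
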