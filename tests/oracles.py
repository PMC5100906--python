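"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: superposition uses
the Horn quaternion eigenvalue method instead of SVD alignment, clustering
is a plain-Python list reimplementation, and the CVs are computed term by
term from their definitions.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition via Horn's quaternion method.

    Returns (rotation, translation, rmsd) minimising the least-squares
    deviation of mobile onto reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    sq = max((mc ** 2).sum() + (rc ** 2).sum() - 2.0 * eigvals[-1], 0.0)
    rmsd = np.sqrt(sq / mobile.shape[0])
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    return rot, trans, float(rmsd)


def brute_rmsd_after_fit(frame_fit, ref_fit, frame_calc, ref_calc) -> float:
    """Fit on one coordinate set, evaluate RMSD on another, all explicit."""
    rot, trans, _ = quaternion_superpose(frame_fit, ref_fit)
    moved = frame_calc @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - ref_calc) ** 2, axis=1))))


def brute_delta_rmsd(frame_fit, frame_calc, ago_fit, ago_calc,
                     ant_fit, ant_calc) -> float:
    """ΔRMSD computed by two explicit fitted RMSDs."""
    r_ago = brute_rmsd_after_fit(frame_fit, ago_fit, frame_calc, ago_calc)
    r_ant = brute_rmsd_after_fit(frame_fit, ant_fit, frame_calc, ant_calc)
    return r_ago - r_ant


def brute_switching(r: float, r0: float, n: int = 8, m: int = 12) -> float:
    """Direct rational form, with the analytic n/m limit at r = r0."""
    u = r / r0
    if abs(u - 1.0) < 1e-12:
        return n / m
    return (1.0 - u ** n) / (1.0 - u ** m)


def brute_salpha(window_coords: list[np.ndarray], template: np.ndarray,
                 r0: float = 0.08) -> float:
    """Per-window α-helix RMSD CV summed explicitly."""
    total = 0.0
    for coords in window_coords:
        _, _, r = quaternion_superpose(coords, template)
        total += brute_switching(r, r0)
    return total


def brute_gromos(distance_matrix: np.ndarray, cutoff: float):
    """Plain-python iterative neighbour-count clustering.

    Returns (clusters, representatives) with lowest-index tie-breaking and
    in-cluster summed-distance medoids.
    """
    n = distance_matrix.shape[0]
    remaining = set(range(n))
    clusters, reps = [], []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if distance_matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(
            j for j in remaining if distance_matrix[best, j] <= cutoff
        )
        rep, rep_sum = None, np.inf
        for i in members:
            s = sum(distance_matrix[i, j] for j in members)
            if s < rep_sum:
                rep, rep_sum = i, s
        clusters.append(members)
        reps.append(rep)
        remaining -= set(members)
    return clusters, reps
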