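"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately written in a different style from the
package (pure-python loops, grid searches, extended precision) so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def cumulative_bin_score(values, edges, n_norm):
    """Linearly-weighted cumulative bin score by explicit loops."""
    k = len(edges)
    total = 0.0
    profile = []
    for rank, edge in enumerate(edges, start=1):
        count = 0
        for v in values:
            if v <= edge:
                count += 1
        p = count / n_norm
        profile.append(p)
        total += (k - rank + 1) * p
    return 2.0 * total / (k * (k + 1)), tuple(profile)


def mean_threshold_fraction(distances, thresholds, n_norm):
    """GDT-style mean fraction under each threshold, by explicit loops."""
    fractions = []
    for t in thresholds:
        count = sum(1 for d in distances if d <= t)
        fractions.append(count / n_norm)
    return sum(fractions) / len(fractions), tuple(fractions)


def angle_between(u, v):
    """Angle between two vectors via arccos in extended precision."""
    u = np.asarray(u, dtype=np.longdouble)
    v = np.asarray(v, dtype=np.longdouble)
    c = (u @ v) / (np.sqrt(u @ u) * np.sqrt(v @ v))
    c = min(max(c, np.longdouble(-1.0)), np.longdouble(1.0))
    return float(np.arccos(c))


def dihedral_gram_schmidt(p0, p1, p2, p3):
    """Signed dihedral about p1-p2 via Gram-Schmidt plane projections, (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    axis = p2 - p1
    axis = axis / np.linalg.norm(axis)
    v0 = p0 - p1
    v3 = p3 - p2
    w0 = v0 - (v0 @ axis) * axis
    w3 = v3 - (v3 @ axis) * axis
    w0 /= np.linalg.norm(w0)
    w3 /= np.linalg.norm(w3)
    cos_a = float(np.clip(w0 @ w3, -1.0, 1.0))
    angle = math.acos(cos_a)
    # sign: positive when w3 is counterclockwise of w0 about the axis
    if float(np.dot(np.cross(w0, w3), axis)) < 0:
        angle = -angle
    if angle == -math.pi:
        angle = math.pi
    return angle


def rotation_about(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def ccw_dihedral_grid(u1, r_vec, u2, n_grid=50_000):
    """Counterclockwise dihedral of u2 about r relative to u1, by grid search.

    Finds the rotation angle about the displacement axis that best aligns the
    rotated in-plane component of u1 with that of u2 -- a direct enactment of
    the definition.
    """
    r_hat = np.asarray(r_vec, dtype=float)
    r_hat = r_hat / np.linalg.norm(r_hat)

    def in_plane(v):
        v = np.asarray(v, dtype=float)
        w = v - (v @ r_hat) * r_hat
        return w / np.linalg.norm(w)

    a = in_plane(u1)
    b = in_plane(u2)
    best_phi, best_dot = 0.0, -np.inf
    for i in range(n_grid):
        phi = 2.0 * math.pi * i / n_grid
        rotated = rotation_about(r_hat, phi) @ a
        d = float(rotated @ b)
        if d > best_dot:
            best_dot, best_phi = d, phi
    return best_phi


def rmsd_after(rotation, a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    mapped = (a - ca) @ rotation.T + cb
    diff = mapped - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def kabsch_grid_rmsd(a, b, coarse=96, levels=4, fine=20):
    """Minimum superposition RMSD by dense grid search over rotations.

    Rotations are parametrized as ZYZ Euler angles on a dense global grid,
    followed by shrinking-box refinement around the best cell.  Centroids
    are matched exactly, which is optimal for any fixed rotation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def batch_rmsd(alphas, betas, gammas):
        grid = np.stack(
            np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        ca_, sa = np.cos(grid[:, 0]), np.sin(grid[:, 0])
        cb_, sb = np.cos(grid[:, 1]), np.sin(grid[:, 1])
        cg, sg = np.cos(grid[:, 2]), np.sin(grid[:, 2])
        m = len(grid)
        rz1 = np.zeros((m, 3, 3))
        rz1[:, 0, 0], rz1[:, 0, 1], rz1[:, 1, 0], rz1[:, 1, 1], rz1[:, 2, 2] = ca_, -sa, sa, ca_, 1.0
        ry = np.zeros((m, 3, 3))
        ry[:, 0, 0], ry[:, 0, 2], ry[:, 1, 1], ry[:, 2, 0], ry[:, 2, 2] = cb_, sb, 1.0, -sb, cb_
        rz2 = np.zeros((m, 3, 3))
        rz2[:, 0, 0], rz2[:, 0, 1], rz2[:, 1, 0], rz2[:, 1, 1], rz2[:, 2, 2] = cg, -sg, sg, cg, 1.0
        rotations = np.einsum("mij,mjk,mkl->mil", rz1, ry, rz2)
        mapped = np.einsum("mij,kj->mki", rotations, a0)
        diff = mapped - b0[None]
        values = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
        best = int(np.argmin(values))
        return float(values[best]), grid[best]

    best_value, best_angles = batch_rmsd(
        np.linspace(0.0, 2.0 * math.pi, coarse, endpoint=False),
        np.linspace(0.0, math.pi, coarse),
        np.linspace(0.0, 2.0 * math.pi, coarse, endpoint=False),
    )
    widths = np.array([2.0 * math.pi, math.pi, 2.0 * math.pi]) * (4.0 / coarse)
    for _ in range(levels):
        value, angles = batch_rmsd(
            *(
                np.linspace(best_angles[i] - widths[i] / 2.0,
                            best_angles[i] + widths[i] / 2.0, fine)
                for i in range(3)
            )
        )
        if value < best_value:
            best_value, best_angles = value, angles
        widths = widths * (4.0 / fine)
    return best_value


def wrapped_rms(x1, x2):
    """Angular RMSD by explicit loops over wrapped differences."""
    total = 0.0
    for a, b in zip(x1, x2):
        delta = abs(b - a) % (2.0 * math.pi)
        delta = min(delta, 2.0 * math.pi - delta)
        total += delta * delta
    return math.sqrt(total / len(x1))
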