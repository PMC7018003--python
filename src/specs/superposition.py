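"""Least-squares rigid superposition and the GDT-style multi-superposition search.

``kabsch`` is the standard SVD solution of the orthogonal Procrustes problem
with the reflection branch corrected.  ``gdt_search`` approximates, for each
distance threshold, the largest set of paired C-alpha atoms simultaneously
superimposable within that threshold, using an iterative seed-and-extend
heuristic (contiguous seed windows of 3/5/7 residues plus the full chain,
each refined by refitting on the residues currently inside the cutoff).  It
also selects the single reference superposition subsequently used to carry
side-chain atoms into the native frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["RigidTransform", "SuperpositionResult", "SuperpositionError", "kabsch", "gdt_search"]

_ORTHO_TOL = 1e-9

SEED_WINDOW_LENGTHS = (3, 5, 7)
MAX_REFINE_ITERATIONS = 10


class SuperpositionError(ValueError):
    """Raised on invalid superposition input (too few points, length mismatch)."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to a 3-vector or an (n, 3) array of coordinates."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class SuperpositionResult:
    """One superposition with the per-pair distances and threshold counts it induces."""

    transform: RigidTransform
    ca_distances: np.ndarray
    counts_under: dict[float, int]
    rmsd_fit: float


def kabsch(
    coords_a: Sequence[Sequence[float]] | np.ndarray,
    coords_b: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of *coords_a* onto *coords_b*.

    Returns the proper rotation + translation minimizing the RMSD of the
    mapped first point set to the second, and that minimal RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError(f"point sets must share shape (n, 3); got {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise SuperpositionError(f"need at least 3 points, got {len(a)}")

    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    h = (a - centroid_a).T @ (b - centroid_b)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    if sign == 0:  # pragma: no cover - degenerate rank
        sign = 1.0
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = centroid_b - rotation @ centroid_a

    transform = RigidTransform(rotation=rotation, translation=translation)
    diff = transform.apply(a) - b
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return transform, rmsd


def _evaluate_candidate(
    transform: RigidTransform,
    rmsd_fit: float,
    model_ca: np.ndarray,
    native_ca: np.ndarray,
    thresholds: Sequence[float],
) -> SuperpositionResult:
    distances = np.linalg.norm(transform.apply(model_ca) - native_ca, axis=1)
    counts = {float(t): int(np.count_nonzero(distances <= t)) for t in thresholds}
    return SuperpositionResult(
        transform=transform,
        ca_distances=distances,
        counts_under=counts,
        rmsd_fit=rmsd_fit,
    )


def _refine(
    seed_idx: np.ndarray,
    model_ca: np.ndarray,
    native_ca: np.ndarray,
    threshold: float,
) -> tuple[RigidTransform, float] | None:
    """Fit on the seed, then iterate fit-on-inliers until stable."""
    current = seed_idx
    transform, rmsd = kabsch(model_ca[current], native_ca[current])
    for _ in range(MAX_REFINE_ITERATIONS):
        distances = np.linalg.norm(transform.apply(model_ca) - native_ca, axis=1)
        inliers = np.flatnonzero(distances <= threshold)
        if len(inliers) < 3:
            break
        if len(inliers) == len(current) and np.array_equal(inliers, current):
            break
        current = inliers
        transform, rmsd = kabsch(model_ca[current], native_ca[current])
    return transform, rmsd


def gdt_search(
    model_ca: np.ndarray,
    native_ca: np.ndarray,
    thresholds: Sequence[float],
) -> tuple[dict[float, int], SuperpositionResult]:
    """Per-threshold maximal superimposable counts and the reference superposition.

    For each threshold the reported count is the best over all candidate
    superpositions found by the seed-and-extend search.  The returned
    reference is the single candidate with the highest count at the largest
    threshold, ties broken by counts at successively smaller thresholds and
    then by lowest fit RMSD; it is the frame in which side-chain geometry is
    subsequently measured.
    """
    model_ca = np.asarray(model_ca, dtype=float)
    native_ca = np.asarray(native_ca, dtype=float)
    if model_ca.shape != native_ca.shape or model_ca.ndim != 2 or model_ca.shape[1] != 3:
        raise SuperpositionError("paired coordinate arrays must share shape (n, 3)")
    n = len(model_ca)
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired residues, got {n}")
    thresholds = sorted(float(t) for t in thresholds)
    if not thresholds:
        raise SuperpositionError("no thresholds given")

    full_idx = np.arange(n)
    seeds: list[np.ndarray] = [full_idx]
    for length in SEED_WINDOW_LENGTHS:
        if length > n:
            continue
        for start in range(0, n - length + 1):
            seeds.append(np.arange(start, start + length))

    candidates: list[SuperpositionResult] = []
    full_transform, full_rmsd = kabsch(model_ca, native_ca)
    candidates.append(
        _evaluate_candidate(full_transform, full_rmsd, model_ca, native_ca, thresholds)
    )
    for threshold in thresholds:
        for seed in seeds:
            refined = _refine(seed, model_ca, native_ca, threshold)
            if refined is None:
                continue
            transform, rmsd = refined
            candidates.append(
                _evaluate_candidate(transform, rmsd, model_ca, native_ca, thresholds)
            )

    max_counts = {
        t: max(c.counts_under[t] for c in candidates) for t in thresholds
    }

    def _preference(c: SuperpositionResult) -> tuple:
        return tuple(c.counts_under[t] for t in reversed(thresholds)) + (-c.rmsd_fit,)

    reference = max(candidates, key=_preference)
    return max_counts, reference
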