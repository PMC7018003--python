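"""Chi1 torsion angles and (normalized) angular RMSD between model and native.

Chi1 is the signed dihedral N-CA-CB-X, where X is the residue-type-specific
gamma-position atom.  Per-target accuracy is the root mean square of the
chi1 differences wrapped to [0, pi], mapped onto [0, 1] by a Lorentzian-style
normalization with half-point at pi/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Residue, Structure, pair_residues

__all__ = [
    "CHI1_FOURTH_ATOM",
    "Chi1Record",
    "AngularRmsdResult",
    "compute_chi1",
    "chi1_records",
    "angular_rmsd",
    "normalized_angular_rmsd",
    "compare_chi1",
]

#: Gamma-position atom completing the N-CA-CB-X chi1 quadruple, per residue type.
CHI1_FOURTH_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}


@dataclass(frozen=True)
class Chi1Record:
    """Chi1 of one residue present with defined chi1 in both structures."""

    residue_id: tuple[str, int, str]
    res_name: str
    chi1_model: float
    chi1_native: float

    @property
    def wrapped_difference(self) -> float:
        delta = abs(self.chi1_model - self.chi1_native)
        return min(delta, 2.0 * math.pi - delta)


@dataclass(frozen=True)
class AngularRmsdResult:
    armsd: float
    normalized: float
    n: int


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral about p1-p2, in (-pi, pi]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    angle = math.atan2(float(np.dot(np.cross(b1, v), w)), float(np.dot(v, w)))
    return math.pi if angle == -math.pi else angle


def compute_chi1(res: Residue) -> float | None:
    """Chi1 of *res* in radians within (-pi, pi], or ``None`` when undefined.

    Undefined for glycine/alanine and whenever any of the four required
    atoms is missing.
    """
    fourth = CHI1_FOURTH_ATOM.get(res.res_name)
    if fourth is None:
        return None
    atoms = [res.get("N"), res.get("CA"), res.get("CB"), res.get(fourth)]
    if any(a is None for a in atoms):
        return None
    return _dihedral(*(a.coord for a in atoms))


def chi1_records(model: Structure, native: Structure) -> list[Chi1Record]:
    """Chi1 pairs for every aligned residue with chi1 defined in both structures."""
    correspondence = pair_residues(model, native)
    records: list[Chi1Record] = []
    for i, j in correspondence.pairs:
        chi_model = compute_chi1(model.residues[i])
        chi_native = compute_chi1(native.residues[j])
        if chi_model is None or chi_native is None:
            continue
        res = native.residues[j]
        records.append(
            Chi1Record(
                residue_id=res.id,
                res_name=res.res_name,
                chi1_model=chi_model,
                chi1_native=chi_native,
            )
        )
    return records


def angular_rmsd(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Root mean square of angle differences wrapped to [0, pi]; inputs in radians."""
    a1 = np.asarray(x1, dtype=float)
    a2 = np.asarray(x2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("angle vectors must be 1-d and of equal length")
    if a1.size == 0:
        raise ValueError("angle vectors must be non-empty")
    delta = np.abs(a2 - a1) % (2.0 * np.pi)
    wrapped = np.minimum(delta, 2.0 * np.pi - delta)
    return float(np.sqrt(np.mean(wrapped**2)))


def normalized_angular_rmsd(armsd: float) -> float:
    """Map an angular RMSD (radians) to [0, 1]; 0 -> 1, pi/4 -> 0.5."""
    if armsd < 0:
        raise ValueError("angular RMSD must be non-negative")
    return 1.0 / (1.0 + (armsd / (math.pi / 4.0)) ** 2)


def compare_chi1(model: Structure, native: Structure) -> tuple[AngularRmsdResult, list[Chi1Record]]:
    """Target-level chi1 angular RMSD between *model* and *native*."""
    records = chi1_records(model, native)
    if not records:
        raise ValueError("no residue has chi1 defined in both structures")
    armsd = angular_rmsd(
        [r.chi1_model for r in records], [r.chi1_native for r in records]
    )
    return AngularRmsdResult(
        armsd=armsd, normalized=normalized_angular_rmsd(armsd), n=len(records)
    ), records
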