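"""United-residue representation and aligned-pair geometry.

Each residue is reduced to its C-alpha atom plus a single side-chain
characteristic point, the unweighted centroid of its side-chain heavy atoms.
An aligned model/native residue pair is then fully described by five
quantities: the C-alpha distance, the centroid distance, the two planar
angles each virtual C-alpha->centroid bond makes with the inter-structure
centroid displacement, and the counterclockwise dihedral between the two
bonds about that displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .structure_io import Residue, StructureError

if TYPE_CHECKING:  # pragma: no cover
    from .superposition import RigidTransform

__all__ = ["URResidue", "URPairGeometry", "ConversionError", "to_united_residue", "pair_geometry"]

#: Below this (Angstrom) a displacement or bond vector is treated as zero.
DEFAULT_EPS = 1e-6

_COLLINEAR_TOL = 1e-9


class ConversionError(StructureError):
    """Raised when a residue cannot be converted to united-residue form."""


@dataclass(frozen=True)
class URResidue:
    """A residue as a C-alpha point plus a side-chain centroid point.

    When the residue has no side-chain heavy atom (glycine), ``sc`` equals
    ``ca`` and ``has_distinct_sc`` is false.
    """

    ca: np.ndarray
    sc: np.ndarray
    has_distinct_sc: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        object.__setattr__(self, "sc", np.asarray(self.sc, dtype=float))


@dataclass(frozen=True)
class URPairGeometry:
    """The five quantities describing one aligned residue pair.

    Distances in Angstrom; angles in radians, with ``phi`` in [0, 2*pi).
    ``angles_defined`` is false (and all angles zero) for degenerate
    geometry: coincident centroids, missing side-chain, or a zero-length
    virtual bond.
    """

    d: float
    r: float
    theta1: float
    theta2: float
    phi: float
    angles_defined: bool


def to_united_residue(res: Residue) -> URResidue:
    """Reduce *res* to its C-alpha and side-chain-centroid points."""
    ca = res.ca_coord
    if ca is None:
        raise ConversionError(
            f"residue {res.res_name} {res.chain_id}{res.seq_num}{res.icode}: no CA atom"
        )
    sc_atoms = res.sidechain_coords()
    if len(sc_atoms) == 0:
        return URResidue(ca=ca, sc=ca.copy(), has_distinct_sc=False)
    return URResidue(ca=ca, sc=sc_atoms.mean(axis=0), has_distinct_sc=True)


def _unit(v: np.ndarray, eps: float) -> np.ndarray | None:
    n = float(np.linalg.norm(v))
    if n < eps:
        return None
    return v / n


def pair_geometry(
    model: URResidue,
    native: URResidue,
    transform: "RigidTransform | None" = None,
    eps: float = DEFAULT_EPS,
) -> URPairGeometry:
    """Compute the five-parameter geometry of an aligned residue pair.

    *transform* maps model coordinates into the native frame (identity when
    ``None``).  The centroid displacement is taken model -> native; the
    planar angles are measured between each unit bond vector and that
    displacement, and the dihedral is the counterclockwise rotation of the
    native bond about the displacement relative to the model bond, mapped to
    [0, 2*pi).
    """
    if transform is not None:
        m_ca = transform.apply(model.ca)
        m_sc = transform.apply(model.sc)
    else:
        m_ca, m_sc = model.ca, model.sc

    d = float(np.linalg.norm(m_ca - native.ca))

    r_vec = native.sc - m_sc
    r = float(np.linalg.norm(r_vec))

    degenerate = URPairGeometry(d=d, r=r, theta1=0.0, theta2=0.0, phi=0.0, angles_defined=False)
    if not (model.has_distinct_sc and native.has_distinct_sc) or r < eps:
        return degenerate

    r_hat = r_vec / r
    u1 = _unit(m_sc - m_ca, eps)
    u2 = _unit(native.sc - native.ca, eps)
    if u1 is None or u2 is None:
        return degenerate

    cos1 = float(np.clip(np.dot(u1, r_hat), -1.0, 1.0))
    cos2 = float(np.clip(np.dot(u2, r_hat), -1.0, 1.0))
    theta1 = float(np.arccos(cos1))
    theta2 = float(np.arccos(cos2))

    sin_prod = np.sin(theta1) * np.sin(theta2)
    if sin_prod < _COLLINEAR_TOL:
        # torsion degenerates to the inter-bond angle
        phi = 0.0 if float(np.dot(u1, u2)) >= 0.0 else float(np.pi)
        return URPairGeometry(d=d, r=r, theta1=theta1, theta2=theta2, phi=phi, angles_defined=True)

    # signed dihedral of u2 about r_hat relative to u1, via in-plane projections
    a = u1 - cos1 * r_hat
    b = u2 - cos2 * r_hat
    phi = float(np.arctan2(float(np.dot(np.cross(a, b), r_hat)), float(np.dot(a, b))))
    if phi < 0.0:
        phi += 2.0 * np.pi
    if phi >= 2.0 * np.pi:
        phi = 0.0
    return URPairGeometry(d=d, r=r, theta1=theta1, theta2=theta2, phi=phi, angles_defined=True)
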