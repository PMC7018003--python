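"""Deterministic synthetic model/native structure pairs.

Generates idealized single-chain structures (consecutive C-alpha spacing of
3.8 Angstrom, 1-4 side-chain heavy atoms per residue, configurable glycine
fraction) and perturbed decoys with controllable C-alpha noise, side-chain
rotation about an axis through the C-alpha, side-chain displacement, and
whole-domain displacement.  Everything is seeded; the same spec always
produces byte-identical structures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .structure_io import BACKBONE_ATOMS, AtomRecord, Residue, Structure

__all__ = ["FixtureSpec", "make_native", "make_decoy", "write_pdb"]

CA_CA_DISTANCE = 3.8

# residue name -> ordered side-chain atom names (beyond the backbone)
_SIDECHAIN_TEMPLATES: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "VAL": ("CB", "CG1", "CG2"),
    "THR": ("CB", "OG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
}

_NON_GLY = tuple(name for name in _SIDECHAIN_TEMPLATES if name != "GLY")

_ELEMENT_BY_PREFIX = {"C": "C", "O": "O", "S": "S", "N": "N"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic native/decoy pair."""

    n_residues: int
    fold: str = "helix"  # "helix" or "extended"
    ca_noise_sigma: float = 0.0
    sc_rotation_deg: float = 0.0
    sc_displacement: float = 0.0
    domain_split: tuple[int, float] | None = None
    gly_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.fold not in ("helix", "extended"):
            raise ValueError(f"unknown fold {self.fold!r}")
        for name in ("ca_noise_sigma", "sc_rotation_deg", "sc_displacement"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gly_fraction <= 1.0:
            raise ValueError("gly_fraction must be in [0, 1]")


def _ca_trace(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_residues
    if spec.fold == "helix":
        rise = 1.5
        omega = math.radians(100.0)
        radius = math.sqrt(CA_CA_DISTANCE**2 - rise**2) / (2.0 * math.sin(omega / 2.0))
        i = np.arange(n)
        return np.column_stack(
            [radius * np.cos(omega * i), radius * np.sin(omega * i), rise * i]
        )
    # pleated, slightly non-planar strand; steps have exact length
    coords = [np.zeros(3)]
    for i in range(n - 1):
        direction = np.array([1.0, 0.35 * (-1.0) ** i, 0.15 * math.sin(0.9 * i)])
        direction /= np.linalg.norm(direction)
        coords.append(coords[-1] + CA_CA_DISTANCE * direction)
    return np.asarray(coords)


def _local_frame(trace: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = max(i - 1, 0)
    hi = min(i + 1, len(trace) - 1)
    tangent = trace[hi] - trace[lo]
    tangent /= np.linalg.norm(tangent)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = np.cross(tangent, ref)
    normal /= np.linalg.norm(normal)
    binormal = np.cross(tangent, normal)
    return tangent, normal, binormal


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _element_of(atom_name: str) -> str:
    return _ELEMENT_BY_PREFIX.get(atom_name[0], "C")


def make_native(spec: FixtureSpec) -> Structure:
    """Build a deterministic idealized native structure from *spec*."""
    rng = np.random.default_rng(spec.seed)
    trace = _ca_trace(spec)
    n = spec.n_residues

    n_gly = int(round(spec.gly_fraction * n))
    gly_positions = set(rng.choice(n, size=n_gly, replace=False)) if n_gly else set()
    names = [
        "GLY" if i in gly_positions else _NON_GLY[rng.integers(len(_NON_GLY))]
        for i in range(n)
    ]

    residues: list[Residue] = []
    for i, (ca, res_name) in enumerate(zip(trace, names)):
        tangent, normal, binormal = _local_frame(trace, i)
        residue = Residue(chain_id="A", seq_num=i + 1, icode="", res_name=res_name)

        def _add(name: str, coord: np.ndarray) -> None:
            residue.atoms[name] = AtomRecord(
                atom_name=name, element=_element_of(name), coord=coord
            )

        n_dir = -tangent + 0.4 * normal
        c_dir = tangent + 0.4 * normal
        _add("N", ca + 1.46 * n_dir / np.linalg.norm(n_dir))
        _add("CA", ca.copy())
        c_pos = ca + 1.52 * c_dir / np.linalg.norm(c_dir)
        _add("C", c_pos)
        _add("O", c_pos + 1.23 * binormal)

        grow = -normal + 0.25 * rng.standard_normal(3)
        grow /= np.linalg.norm(grow)
        position = ca
        for atom_name in _SIDECHAIN_TEMPLATES[res_name]:
            step = grow + 0.35 * rng.standard_normal(3)
            step /= np.linalg.norm(step)
            position = position + 1.52 * step
            _add(atom_name, position)
        residues.append(residue)

    return Structure(residues=residues, source_label=f"synthetic(seed={spec.seed})")


#: Tilt of the side-chain rotation axis off the CA->centroid bond, degrees.
#: Keeping it below 30 pins both planar angles inside a single bin for any
#: rotation magnitude, so increasing the rotation degrades the score through
#: the centroid-distance (and dihedral) terms monotonically.
SC_ROTATION_AXIS_TILT_DEG = 25.0


def _sc_rotation_axis(res: Residue) -> np.ndarray:
    """Axis through the C-alpha, tilted a fixed angle off the centroid bond."""
    sc_atoms = res.sidechain_coords()
    bond = sc_atoms.mean(axis=0) - res.atoms["CA"].coord
    norm = np.linalg.norm(bond)
    if norm < 1e-9:
        return np.array([0.0, 0.0, 1.0])
    bond = bond / norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(bond[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(bond, ref)
    perp /= np.linalg.norm(perp)
    tilt = math.radians(SC_ROTATION_AXIS_TILT_DEG)
    return math.cos(tilt) * bond + math.sin(tilt) * perp


def make_decoy(native: Structure, spec: FixtureSpec) -> Structure:
    """Perturb a copy of *native* according to *spec*.

    With all perturbation magnitudes zero the decoy is identical to the
    native; with ``ca_noise_sigma == 0`` the C-alpha traces coincide exactly.
    """
    rng = np.random.default_rng([spec.seed, 0xDEC0])
    angle = math.radians(spec.sc_rotation_deg)

    residues: list[Residue] = []
    for idx, res in enumerate(native.residues):
        shift = np.zeros(3)
        if spec.domain_split is not None:
            split_index, displacement = spec.domain_split
            if idx >= split_index:
                shift = shift + np.array([displacement, 0.0, 0.0])
        if spec.ca_noise_sigma > 0:
            shift = shift + spec.ca_noise_sigma * rng.standard_normal(3)

        ca = res.atoms["CA"].coord + shift

        sc_rotation = None
        if angle != 0.0 and res.has_sidechain:
            sc_rotation = _rotation_about_axis(_sc_rotation_axis(res), angle)

        sc_shift = np.zeros(3)
        if spec.sc_displacement > 0 and res.has_sidechain:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            sc_shift = spec.sc_displacement * direction

        new_res = Residue(
            chain_id=res.chain_id, seq_num=res.seq_num, icode=res.icode,
            res_name=res.res_name,
        )
        for name, atom in res.atoms.items():
            coord = atom.coord + shift
            if name not in BACKBONE_ATOMS:
                if sc_rotation is not None:
                    coord = ca + sc_rotation @ (coord - ca)
                coord = coord + sc_shift
            new_res.atoms[name] = replace(atom, coord=coord)
        residues.append(new_res)

    return Structure(residues=residues, source_label=f"decoy(seed={spec.seed})")


def _format_atom_line(serial: int, atom: AtomRecord, res: Residue) -> str:
    name = atom.atom_name
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{res.res_name:>3s} {res.chain_id:1s}"
        f"{res.seq_num:4d}{res.icode or ' ':1s}   "
        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, path: Union[str, os.PathLike], seed: int | None = None) -> None:
    """Write *structure* as fixed-column ATOM records; round-trips through parse_pdb."""
    lines: list[str] = []
    if seed is not None:
        lines.append(f"REMARK 250 SYNTHETIC FIXTURE SEED {seed}")
    serial = 0
    order = ["N", "CA", "C", "O"]
    for res in structure.residues:
        names = [n for n in order if n in res.atoms]
        names += [n for n in res.atoms if n not in order]
        for name in names:
            serial += 1
            lines.append(_format_atom_line(serial, res.atoms[name], res))
    lines.append("END")
    try:
        with open(path, "w") as handle:
            handle.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB to {path!r}: {exc}") from exc
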