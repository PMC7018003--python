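from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from specs import FixtureSpec, Structure, make_decoy, make_native
from specs.structure_io import Residue


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rng.uniform(-50.0, 50.0, size=3)
    return rotation, translation


def transform_structure(structure: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply a rigid motion to every atom of a structure."""
    residues = []
    for res in structure.residues:
        new = Residue(res.chain_id, res.seq_num, res.icode, res.res_name)
        for name, atom in res.atoms.items():
            new.atoms[name] = replace(atom, coord=rotation @ atom.coord + translation)
        residues.append(new)
    return Structure(residues, structure.source_label + "+rigid")


@pytest.fixture
def helix_native() -> Structure:
    return make_native(FixtureSpec(n_residues=25, fold="helix", gly_fraction=0.12, seed=11))


@pytest.fixture
def noisy_decoy(helix_native) -> Structure:
    spec = FixtureSpec(n_residues=25, ca_noise_sigma=0.8, sc_rotation_deg=40.0, seed=11)
    return make_decoy(helix_native, spec)


def structure_pair(seed: int, n: int = 20, sigma: float = 0.7, rotation: float = 35.0,
                   gly_fraction: float = 0.1, fold: str = "helix"):
    spec = FixtureSpec(n_residues=n, fold=fold, gly_fraction=gly_fraction, seed=seed)
    native = make_native(spec)
    decoy = make_decoy(
        native,
        FixtureSpec(n_residues=n, ca_noise_sigma=sigma, sc_rotation_deg=rotation, seed=seed),
    )
    return decoy, native


ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.458   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
"""
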