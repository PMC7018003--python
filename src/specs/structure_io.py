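"""PDB input and model/native residue correspondence.

Parsing is delegated to Bio.PDB; the resulting hierarchy is flattened into a
minimal heavy-atom structure model.  Only the first MODEL of a multi-model
file is retained; hydrogens, HETATM records and waters are excluded, and
alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ResidueCorrespondence",
    "StructureError",
    "ParseError",
    "EmptyStructureError",
    "CorrespondenceError",
    "BACKBONE_ATOMS",
    "STANDARD_AA",
    "parse_pdb",
    "pair_residues",
]

#: Main-chain atom names never included in the side-chain centroid.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class StructureError(Exception):
    """Base class for structure-handling errors."""


class ParseError(StructureError):
    """Raised when a PDB source cannot be parsed."""


class EmptyStructureError(StructureError):
    """Raised when a source contains no usable ATOM records."""


class CorrespondenceError(StructureError):
    """Raised when two structures share no residue identifiers."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: PDB atom name, element and coordinates in Angstrom."""

    atom_name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.atom_name!r}: coord must be 3 finite values")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """A residue as an ordered mapping of atom name -> AtomRecord."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def get(self, atom_name: str) -> AtomRecord | None:
        return self.atoms.get(atom_name)

    @property
    def ca_coord(self) -> np.ndarray | None:
        atom = self.atoms.get("CA")
        return atom.coord if atom is not None else None

    def sidechain_coords(self) -> np.ndarray:
        """Coordinates of all heavy atoms outside the backbone set, (m, 3)."""
        coords = [a.coord for name, a in self.atoms.items() if name not in BACKBONE_ATOMS]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)

    @property
    def has_sidechain(self) -> bool:
        return any(name not in BACKBONE_ATOMS for name in self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.res_name} {self.chain_id}{self.seq_num}{self.icode}>"


@dataclass
class Structure:
    """Ordered collection of residues from a single model of a PDB source."""

    residues: list[Residue]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, index: int) -> Residue:
        return self.residues[index]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Aligned (model index, native index) pairs plus native normalization counts.

    ``n_native`` counts every residue of the native structure and ``n_native_sc``
    those bearing at least one side-chain heavy atom, regardless of whether the
    residue could be paired; missing model residues are thereby penalized.
    """

    pairs: tuple[tuple[int, int], ...]
    n_native: int
    n_native_sc: int

    def __len__(self) -> int:
        return len(self.pairs)


def _source_handle(source: Union[str, os.PathLike]) -> tuple[io.TextIOBase, str]:
    if isinstance(source, os.PathLike):
        source = os.fspath(source)
    if "\n" in source:
        return io.StringIO(source), "<string>"
    if not os.path.exists(source):
        raise IOError(f"PDB source not found: {source!r}")
    return open(source), os.path.basename(source)


def parse_pdb(
    source: Union[str, os.PathLike],
    *,
    map_mse: bool = False,
) -> Structure:
    """Parse ATOM records of the first model into a heavy-atom :class:`Structure`.

    Parameters
    ----------
    source:
        Path to a PDB file, or the PDB text itself (detected by the presence
        of a newline).
    map_mse:
        If true, selenomethionine (MSE, usually a HETATM) is accepted and
        renamed to MET; otherwise all non-standard residues are dropped with
        a warning.

    Raises
    ------
    IOError
        If a path source is unreadable.
    ParseError
        On malformed records (the underlying message names the line).
    EmptyStructureError
        If no usable ATOM records remain after filtering.
    """
    handle, label = _source_handle(source)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio_structure = parser.get_structure(label, handle)
    except PDBConstructionException as exc:
        raise ParseError(f"{label}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"{label}: malformed numeric field ({exc})") from exc
    finally:
        handle.close()

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"{label}: no ATOM records found")
    model = models[0]

    residues: list[Residue] = []
    seen_ids: set[tuple[str, int, str]] = set()
    for chain in model:
        for bio_res in chain:
            hetflag, seq_num, icode = bio_res.id
            res_name = bio_res.get_resname().strip()
            if hetflag != " ":
                if map_mse and res_name == "MSE":
                    res_name = "MET"
                else:
                    continue  # HETATM (incl. waters)
            if res_name == "MSE" and map_mse:
                res_name = "MET"
            if res_name not in STANDARD_AA:
                warnings.warn(
                    f"{label}: dropping non-standard residue {res_name} "
                    f"{chain.id}{seq_num}{icode.strip()}"
                )
                continue
            residue = Residue(
                chain_id=chain.id,
                seq_num=seq_num,
                icode=icode.strip(),
                res_name=res_name,
            )
            for atom in bio_res:
                # disordered atoms expose their highest-occupancy child here
                element = (atom.element or "").strip().upper()
                if element in _HYDROGEN_ELEMENTS:
                    continue
                name = atom.get_name().strip()
                if name in residue.atoms:
                    continue
                residue.atoms[name] = AtomRecord(
                    atom_name=name,
                    element=element,
                    coord=np.array(atom.coord, dtype=float),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    altloc=atom.get_altloc().strip(),
                )
            if not residue.atoms:
                continue
            if residue.id in seen_ids:
                warnings.warn(f"{label}: duplicate residue id {residue.id}; keeping first")
                continue
            seen_ids.add(residue.id)
            residues.append(residue)

    if not residues:
        raise EmptyStructureError(f"{label}: no ATOM records found")
    return Structure(residues=residues, source_label=label)


def pair_residues(model: Structure, native: Structure) -> ResidueCorrespondence:
    """Match residues of *model* and *native* by (chain, seq_num, icode).

    Pairs whose residue names disagree are dropped with a warning.  The
    normalization counts ``n_native`` / ``n_native_sc`` always reflect the
    full native structure.
    """
    if len(model) == 0 or len(native) == 0:
        raise EmptyStructureError("cannot pair residues of an empty structure")

    model_index = {res.id: i for i, res in enumerate(model.residues)}
    pairs: list[tuple[int, int]] = []
    for j, native_res in enumerate(native.residues):
        i = model_index.get(native_res.id)
        if i is None:
            continue
        if model.residues[i].res_name != native_res.res_name:
            warnings.warn(
                f"residue {native_res.id}: name mismatch "
                f"({model.residues[i].res_name} vs {native_res.res_name}); pair dropped"
            )
            continue
        pairs.append((i, j))

    if not pairs:
        raise CorrespondenceError(
            f"structures {model.source_label!r} and {native.source_label!r} "
            "share no residue identifiers"
        )
    n_native_sc = sum(1 for res in native.residues if res.has_sidechain)
    return ResidueCorrespondence(
        pairs=tuple(pairs),
        n_native=len(native),
        n_native_sc=n_native_sc,
    )
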