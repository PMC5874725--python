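"""Read PDB files into a uniform chain/residue/atom model.

The Gaussian network analysis downstream works on Cα coordinates only, while
interface-target extraction needs every heavy atom, so the in-memory model keeps
both: an ordered residue list per chain (residues without a resolved Cα keep
their sequence slot but are excluded from the elastic network) and the full atom
records per residue.  Parsing is delegated to biotite; this module only shapes
the result and enforces the conventions below.

Conventions
-----------
* Model 1 only for multi-model files.
* Altlocs resolved to the highest-occupancy variant (ties: first in file).
* Waters, ligands and other non-amino-acid residues are dropped; modified
  amino acids (MSE, SEP, ...) are mapped to their parent type when a standard
  mapping exists, else ``UNK``.
* Coordinates are in Å throughout; residue order follows the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "AtomRecord",
    "ResidueModel",
    "ChainModel",
    "DimerModel",
    "parse_structure",
    "residue_ca_distances",
    "write_chain_tsv",
    "STANDARD_AA",
]

#: The 20 standard amino-acid three-letter codes, alphabetical by code.
STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Common modified residues -> parent standard type.  Anything aminoacid-like
# but absent here becomes UNK (kept for geometry, rejected by potential lookup).
_MODIFIED_AA = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "CSO": "CYS", "CSS": "CYS",
    "OCS": "CYS", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "MLY": "LYS",
    "M3L": "LYS", "KCX": "LYS", "LLP": "LYS", "HYP": "PRO", "PCA": "GLU",
    "CME": "CYS", "CSD": "CYS", "MLZ": "LYS", "FME": "MET", "HIC": "HIS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "DAH": "PHE", "TYS": "TYR",
}

_HYDROGEN = frozenset({"H", "D"})


class StructureError(ValueError):
    """Raised for malformed or unusable structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, element, position (Å), occupancy and altloc tag."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise StructureError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclass
class ResidueModel:
    """One residue: position in the chain, author numbering, type and atoms."""

    seq_index: int
    author_id: str
    aa_type: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def ca_coord(self) -> Optional[np.ndarray]:
        """Coordinate of the CA atom, or None if the Cα is not resolved."""
        for atom in self.atoms:
            if atom.name == "CA":
                return atom.coord
        return None

    @property
    def has_ca(self) -> bool:
        return self.ca_coord is not None

    def heavy_coords(self) -> np.ndarray:
        """(k, 3) array of non-hydrogen atom coordinates (may be empty)."""
        coords = [a.coord for a in self.atoms if not a.is_hydrogen]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)


@dataclass
class ChainModel:
    """An ordered protein chain.

    ``length`` counts only residues with a resolved Cα — the "sequence length"
    used by every length-dependent rule downstream — while ``residues`` keeps
    unresolved residues in their sequence slots so that 1D neighbourhood
    spreading respects gaps in the model.
    """

    chain_id: str
    residues: list[ResidueModel] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(1 for r in self.residues if r.has_ca)

    @property
    def n_slots(self) -> int:
        """Total residue slots including residues without a resolved Cα."""
        return len(self.residues)

    def ca_indices(self) -> np.ndarray:
        """seq_index of every residue with a resolved Cα, in chain order."""
        return np.array([r.seq_index for r in self.residues if r.has_ca], dtype=int)

    def ca_array(self) -> np.ndarray:
        """(length, 3) Cα coordinates aligned with :meth:`ca_indices`."""
        coords = [r.ca_coord for r in self.residues if r.has_ca]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)


@dataclass
class DimerModel:
    """Two distinct chains of one complex plus a source label."""

    chain_a: ChainModel
    chain_b: ChainModel
    source: str = ""

    def __post_init__(self) -> None:
        if self.chain_a.chain_id == self.chain_b.chain_id:
            raise StructureError("dimer chains must have distinct chain ids")


def _map_aa(res_name: str) -> str:
    if res_name in STANDARD_AA:
        return res_name
    return _MODIFIED_AA.get(res_name, "UNK")


def _author_id(res_id: int, ins_code: str) -> str:
    return f"{res_id}{ins_code.strip()}"


def _chain_from_atoms(atoms: struc.AtomArray, chain_id: str) -> ChainModel:
    mask = atoms.chain_id == chain_id
    sub = atoms[mask]
    chain = ChainModel(chain_id=chain_id)
    ins = (
        sub.ins_code
        if "ins_code" in sub.get_annotation_categories()
        else np.full(sub.array_length(), "", dtype="U1")
    )
    occ = (
        sub.occupancy
        if "occupancy" in sub.get_annotation_categories()
        else np.ones(sub.array_length())
    )
    seen: dict[tuple[int, str], ResidueModel] = {}
    order: list[ResidueModel] = []
    for i in range(sub.array_length()):
        key = (int(sub.res_id[i]), str(ins[i]))
        residue = seen.get(key)
        if residue is None:
            residue = ResidueModel(
                seq_index=len(order),
                author_id=_author_id(*key),
                aa_type=_map_aa(str(sub.res_name[i])),
            )
            seen[key] = residue
            order.append(residue)
        residue.atoms.append(
            AtomRecord(
                name=str(sub.atom_name[i]),
                element=str(sub.element[i]),
                coord=np.array(sub.coord[i], dtype=float),
                occupancy=float(occ[i]),
            )
        )
    chain.residues = order
    return chain


def parse_structure(
    path: str | Path,
    chain_ids: Optional[Sequence[str]] = None,
) -> DimerModel:
    """Read a PDB file into a :class:`DimerModel`.

    Parameters
    ----------
    path
        PDB file with ATOM records.
    chain_ids
        Pair of chain labels to extract.  If omitted, the file must contain
        exactly two polymer chains.

    Raises
    ------
    StructureError
        Missing file, no polymer chains, wrong chain count, requested chain
        absent, or a chain without any Cα atom.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises on files without coordinates
        raise StructureError(f"{path}: no polymer chains ({exc})") from exc
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no polymer chains")
    present = list(dict.fromkeys(str(c) for c in atoms.chain_id))
    if chain_ids is None:
        if len(present) != 2:
            raise StructureError(
                f"{path}: expected exactly two polymer chains, found {present}"
            )
        chain_ids = present
    if len(chain_ids) != 2:
        raise StructureError("chain_ids must name exactly two chains")
    for cid in chain_ids:
        if cid not in present:
            raise StructureError(f"{path}: chain {cid!r} not found (have {present})")
    chain_a = _chain_from_atoms(atoms, chain_ids[0])
    chain_b = _chain_from_atoms(atoms, chain_ids[1])
    for chain in (chain_a, chain_b):
        if chain.length == 0:
            raise StructureError(f"{path}: chain {chain.chain_id} has no Cα atoms")
    return DimerModel(chain_a=chain_a, chain_b=chain_b, source=str(path))


def residue_ca_distances(chain: ChainModel) -> dict[int, list[tuple[int, float]]]:
    """Per-residue neighbour table of Cα–Cα distances, sorted ascending.

    Returns a mapping ``seq_index -> [(other seq_index, distance Å), ...]``
    over residues with a resolved Cα.
    """
    if chain.length < 2:
        raise StructureError("need at least 2 residues with resolved Cα")
    idx = chain.ca_indices()
    coords = chain.ca_array()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    table: dict[int, list[tuple[int, float]]] = {}
    for row, i in enumerate(idx):
        order = np.argsort(dist[row], kind="stable")
        table[int(i)] = [
            (int(idx[col]), float(dist[row, col])) for col in order if col != row
        ]
    return table


def write_chain_tsv(chain: ChainModel, handle) -> None:
    """Debug writer: TSV of seq_index, author_id, aa_type and Cα coordinates."""
    handle.write("seq_index\tauthor_id\taa_type\tca_x\tca_y\tca_z\n")
    for res in chain.residues:
        if res.has_ca:
            x, y, z = res.ca_coord
            handle.write(
                f"{res.seq_index}\t{res.author_id}\t{res.aa_type}"
                f"\t{x:.3f}\t{y:.3f}\t{z:.3f}\n"
            )
        else:
            handle.write(f"{res.seq_index}\t{res.author_id}\t{res.aa_type}\t.\t.\t.\n")
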