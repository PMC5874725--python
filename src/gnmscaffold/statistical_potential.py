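"""Residue-level pairwise statistical potential for scoring dimer interfaces.

Scores a complex as the sum of pair energies e(a, b) over interchain residue
pairs in contact, in the style of knowledge-based contact potentials such as
Lu & Skolnick's.  The 20×20 energy table is user-supplied input (a plain-text
matrix file); only the relative ordering of decoy energies matters downstream
— lower energy means a more probable complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainModel, DimerModel, STANDARD_AA
from .interface_targets import CONTACT_CUTOFF

__all__ = [
    "PairPotential",
    "load_potential",
    "save_potential",
    "interface_energy",
    "zero_potential",
    "random_potential",
    "CONTACT_ATOM_RULES",
]

CONTACT_ATOM_RULES = ("any_atom", "c_alpha", "c_beta")

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class PairPotential:
    """Symmetric 20×20 residue-pair energy table plus its contact definition."""

    energies: np.ndarray
    contact_cutoff: float = CONTACT_CUTOFF
    contact_atom_rule: str = "any_atom"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (20, 20):
            raise ValueError(f"wrong dimensions: expected 20x20, got {e.shape}")
        if not np.allclose(e, e.T):
            raise ValueError("energy table must be symmetric")
        if self.contact_atom_rule not in CONTACT_ATOM_RULES:
            raise ValueError(f"unknown contact_atom_rule {self.contact_atom_rule!r}")
        self.energies = e

    def lookup(self, aa_a: str, aa_b: str) -> float:
        try:
            return float(self.energies[_AA_INDEX[aa_a], _AA_INDEX[aa_b]])
        except KeyError as exc:
            raise ValueError(f"no potential entry for residue type {exc}") from exc


def _normalize_code(code: str) -> str:
    code = code.upper()
    if code in _AA_INDEX:
        return code
    if code in _ONE_TO_THREE:
        return _ONE_TO_THREE[code]
    raise ValueError(f"unknown residue code {code!r}")


def load_potential(
    path: str | Path,
    contact_cutoff: float = CONTACT_CUTOFF,
    contact_atom_rule: str = "any_atom",
) -> PairPotential:
    """Read a whitespace-delimited 20×20 table with header row and column.

    Residue labels may be one- or three-letter codes in any order.  An
    asymmetric table is symmetrized by averaging, with a warning.
    """
    lines = [
        ln.split()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty potential file")
    header = [_normalize_code(tok) for tok in lines[0]]
    if len(header) != 20 or set(header) != set(STANDARD_AA):
        raise ValueError(f"{path}: wrong dimensions: header must list the 20 amino acids")
    rows = lines[1:]
    if len(rows) != 20 or any(len(r) != 21 for r in rows):
        raise ValueError(f"{path}: wrong dimensions: expected 20 rows of label + 20 values")
    e = np.zeros((20, 20))
    for row in rows:
        a = _normalize_code(row[0])
        for col_label, tok in zip(header, row[1:]):
            e[_AA_INDEX[a], _AA_INDEX[col_label]] = float(tok)
    if not np.allclose(e, e.T):
        warnings.warn(f"{path}: asymmetric potential table; symmetrizing by averaging")
        e = 0.5 * (e + e.T)
    return PairPotential(e, contact_cutoff=contact_cutoff, contact_atom_rule=contact_atom_rule)


def save_potential(pot: PairPotential, path: str | Path) -> None:
    """Write a potential back as a labelled whitespace table (load_potential format)."""
    with open(path, "w") as fh:
        fh.write(" ".join(STANDARD_AA) + "\n")
        for i, aa in enumerate(STANDARD_AA):
            fh.write(aa + " " + " ".join(f"{v:.6f}" for v in pot.energies[i]) + "\n")


def zero_potential() -> PairPotential:
    """All-zero template table."""
    return PairPotential(np.zeros((20, 20)))


def random_potential(seed: int = 0, attractive: bool = True) -> PairPotential:
    """Synthetic random symmetric table; attractive = all energies negative."""
    rng = np.random.default_rng(seed)
    e = rng.uniform(0.2, 2.0, size=(20, 20))
    e = 0.5 * (e + e.T)
    if attractive:
        e = -e
    return PairPotential(e)


def _contact_coords(chain: ChainModel, rule: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-rule atom coordinates and owning residue seq_index."""
    coords, owners = [], []
    for res in chain.residues:
        if rule == "c_alpha":
            xyz = res.ca_coord
            sel = np.empty((0, 3)) if xyz is None else xyz[None, :]
        elif rule == "c_beta":
            cb = next((a.coord for a in res.atoms if a.name == "CB"), None)
            if cb is None:  # glycine (or incomplete side chain): fall back to Cα
                cb = res.ca_coord
            sel = np.empty((0, 3)) if cb is None else cb[None, :]
        else:
            sel = res.heavy_coords()
        if len(sel):
            coords.append(np.atleast_2d(sel))
            owners.append(np.full(len(sel), res.seq_index))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(coords), np.concatenate(owners)


def interface_energy(dimer: DimerModel, pot: PairPotential) -> float:
    """Total contact energy of the interface, each residue pair counted once.

    Raises if a contacting residue pair involves an ``UNK`` residue type.
    """
    xyz_a, own_a = _contact_coords(dimer.chain_a, pot.contact_atom_rule)
    xyz_b, own_b = _contact_coords(dimer.chain_b, pot.contact_atom_rule)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0.0
    type_a = {r.seq_index: r.aa_type for r in dimer.chain_a.residues}
    type_b = {r.seq_index: r.aa_type for r in dimer.chain_b.residues}
    hits = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=pot.contact_cutoff)
    pairs: set[tuple[int, int]] = set()
    for ia, cols in enumerate(hits):
        for ib in cols:
            pairs.add((int(own_a[ia]), int(own_b[ib])))
    energy = 0.0
    for i, j in pairs:
        aa_i, aa_j = type_a[i], type_b[j]
        if aa_i == "UNK" or aa_j == "UNK":
            raise ValueError(f"UNK residue in contact pair ({i}, {j})")
        energy += pot.lookup(aa_i, aa_j)
    return energy
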