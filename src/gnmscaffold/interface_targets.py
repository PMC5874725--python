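"""Ground-truth target extraction: interchain contacts and first-layer residues.

A residue is a *contact* when any of its heavy atoms lies within 4.5 Å of any
heavy atom of the partner chain — 4.5 Å being roughly the diameter of one water
molecule, so contacts are residue pairs that exclude solvent between them.
*First-layer residues* (FLR) are non-contact residues of the same chain within
4.5 Å (atom–atom) of a contact residue; contacts plus FLR form the binding
scaffold that the predictor tries to recover.

Hydrogens are excluded from all distance tests; both boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainModel, DimerModel

__all__ = [
    "TargetSet",
    "extract_contacts",
    "extract_first_layer",
    "extract_targets",
    "target_fraction",
    "CONTACT_CUTOFF",
]

#: Default atom–atom contact cutoff in Å (one water diameter).
CONTACT_CUTOFF = 4.5


@dataclass
class TargetSet:
    """Per-chain prediction ground truth.

    ``contacts`` and ``first_layer`` are disjoint sets of seq_index;
    ``n_targets`` is the size of their union.
    """

    contacts: set[int]
    first_layer: set[int]
    chain_length: int

    def __post_init__(self) -> None:
        if self.contacts & self.first_layer:
            raise ValueError("contacts and first_layer must be disjoint")

    @property
    def n_targets(self) -> int:
        return len(self.contacts) + len(self.first_layer)

    @property
    def all_targets(self) -> set[int]:
        return self.contacts | self.first_layer


def _residue_atoms(chain: ChainModel) -> tuple[np.ndarray, np.ndarray]:
    """Stacked heavy-atom coordinates and the owning seq_index per atom.

    Residues without a resolved Cα are skipped: they cannot be targets.
    """
    coords = []
    owners = []
    for res in chain.residues:
        if not res.has_ca:
            continue
        xyz = res.heavy_coords()
        if len(xyz):
            coords.append(xyz)
            owners.append(np.full(len(xyz), res.seq_index))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(coords), np.concatenate(owners)


def extract_contacts(
    dimer: DimerModel, cutoff: float = CONTACT_CUTOFF
) -> tuple[TargetSet, TargetSet]:
    """Interchain contact residues of both chains (first_layer left empty).

    Residue i of chain A is a contact iff some heavy atom of i is within
    ``cutoff`` of some heavy atom of any residue of chain B; symmetrically
    for B.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz_a, own_a = _residue_atoms(dimer.chain_a)
    xyz_b, own_b = _residue_atoms(dimer.chain_b)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        raise ValueError("both chains need at least one residue with atoms")
    tree_b = cKDTree(xyz_b)
    pairs = cKDTree(xyz_a).query_ball_tree(tree_b, r=cutoff)
    contacts_a: set[int] = set()
    contacts_b: set[int] = set()
    for ia, hits in enumerate(pairs):
        if hits:
            contacts_a.add(int(own_a[ia]))
            contacts_b.update(int(own_b[ib]) for ib in hits)
    ts_a = TargetSet(contacts_a, set(), dimer.chain_a.length)
    ts_b = TargetSet(contacts_b, set(), dimer.chain_b.length)
    return ts_a, ts_b


def extract_first_layer(
    chain: ChainModel, contacts: set[int], cutoff: float = CONTACT_CUTOFF
) -> set[int]:
    """Non-contact residues within ``cutoff`` (atom–atom) of a contact residue."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    valid = {r.seq_index for r in chain.residues}
    if not contacts <= valid:
        raise ValueError(f"contact indices out of range: {sorted(contacts - valid)}")
    if not contacts:
        return set()
    contact_xyz = []
    other_xyz = []
    other_own = []
    for res in chain.residues:
        if not res.has_ca:
            continue
        xyz = res.heavy_coords()
        if not len(xyz):
            continue
        if res.seq_index in contacts:
            contact_xyz.append(xyz)
        else:
            other_xyz.append(xyz)
            other_own.append(np.full(len(xyz), res.seq_index))
    if not contact_xyz or not other_xyz:
        return set()
    tree = cKDTree(np.vstack(contact_xyz))
    own = np.concatenate(other_own)
    hits = tree.query_ball_point(np.vstack(other_xyz), r=cutoff)
    return {int(own[i]) for i, h in enumerate(hits) if h}


def extract_targets(
    dimer: DimerModel, cutoff: float = CONTACT_CUTOFF
) -> tuple[TargetSet, TargetSet]:
    """Complete target sets (contacts + first layer) for both chains."""
    ts_a, ts_b = extract_contacts(dimer, cutoff)
    ts_a.first_layer = extract_first_layer(dimer.chain_a, ts_a.contacts, cutoff)
    ts_b.first_layer = extract_first_layer(dimer.chain_b, ts_b.contacts, cutoff)
    return ts_a, ts_b


def target_fraction(ts: TargetSet) -> float:
    """Fraction of the chain that is a target, n_targets / chain_length."""
    if ts.chain_length <= 0:
        raise ValueError("empty chain")
    return ts.n_targets / ts.chain_length
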