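"""Deterministic toy dimers and rigid-body decoy sets for testing and demos.

Chains are built from Cα traces with one pseudo side-chain atom (``CB``,
1.5 Å from the Cα, alternating orientation) so that all-atom target extraction
has something beyond the backbone to bite on, without rotamer modelling.

Geometries
----------
``strand_pair``
    Two parallel extended strands (3.8 Å Cα spacing) facing each other across
    ``interface_gap``; the contact set is known in closed form and is returned
    alongside the model.
``helix_pair``
    Two parallel ideal α-helices (rise 1.5 Å, 100°/residue, radius 2.3 Å) with
    ``interface_gap`` between their surfaces.
``grid_patch``
    A compact, snake-packed 3D block (the host chain) with a small flat
    boustrophedon patch docked at ``interface_gap`` above the centre of its
    top face.  The block has a densely packed core and looser surface, so its
    fast GNM modes localize the way they do in folded proteins, and the
    docked patch makes a small localized binding site — the situation the
    predictor targets.  The host gets a small seeded in-plane coordinate
    jitter: perfect lattices have translationally degenerate fast modes,
    jittered ones localize.

Decoy sets mirror the structure of published rigid-body docking decoy sets:
one native pose, a configurable number of near-native poses (small in-plane
slides and twists of the ligand chain — the pseudo side chains provide no
steric repulsion, so interpenetrating approach along the interface normal is
excluded as unphysical), and the remainder fully separated far poses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .structure_io import ChainModel, DimerModel, ResidueModel, AtomRecord, STANDARD_AA
from .interface_targets import CONTACT_CUTOFF

__all__ = [
    "FixtureSpec",
    "ToyDimer",
    "make_toy_dimer",
    "make_decoy_set",
    "write_dimer_pdb",
    "write_decoy_set",
    "GEOMETRIES",
]

GEOMETRIES = ("strand_pair", "helix_pair", "grid_patch")

_CA_SPACING = 3.8  # Å, trans peptide Cα-Cα
_SIDECHAIN_LEN = 1.5  # Å, pseudo CB offset


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dimer / decoy set.

    ``perturbation_scale`` bounds near-native rigid moves: translation in Å
    and rotation in degrees.  The same seed always reproduces byte-identical
    output.
    """

    n_a: int = 60
    n_b: int = 12
    geometry: str = "grid_patch"
    interface_gap: float = 5.2
    seed: int = 0
    decoy_count: int = 110
    near_native_count: int = 10
    perturbation_scale: float = 0.5
    grid_width: int = 4

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"invalid geometry name {self.geometry!r}")
        if self.n_a < 10 or self.n_b < 10:
            raise ValueError("chains must have at least 10 residues")
        if self.interface_gap <= 0:
            raise ValueError("interface_gap must be positive")


@dataclass
class ToyDimer:
    """A synthetic dimer plus (when known in closed form) its contact sets."""

    dimer: DimerModel
    expected_contacts_a: Optional[set[int]]
    expected_contacts_b: Optional[set[int]]


def _chain_from_traces(
    chain_id: str,
    ca: np.ndarray,
    cb: np.ndarray,
    aa_offset: int,
) -> ChainModel:
    chain = ChainModel(chain_id=chain_id)
    for i in range(len(ca)):
        res = ResidueModel(
            seq_index=i,
            author_id=str(i + 1),
            aa_type=STANDARD_AA[(aa_offset + 7 * i) % 20],
        )
        res.atoms.append(AtomRecord(name="CA", element="C", coord=ca[i]))
        res.atoms.append(AtomRecord(name="CB", element="C", coord=cb[i]))
        chain.residues.append(res)
    return chain


def _strand(n: int, y: float, cb_sign: float) -> tuple[np.ndarray, np.ndarray]:
    """Extended strand along x at height y; CB alternates ±z."""
    ca = np.stack(
        [np.arange(n) * _CA_SPACING, np.full(n, y), np.zeros(n)], axis=1
    )
    z = _SIDECHAIN_LEN * cb_sign * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    cb = ca + np.stack([np.zeros(n), np.zeros(n), z], axis=1)
    return ca, cb


def _helix(n: int, y0: float) -> tuple[np.ndarray, np.ndarray]:
    """Ideal α-helix along x, axis at (y0, 0); CB radially outward."""
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    t = np.arange(n) * turn
    ca = np.stack(
        [np.arange(n) * rise, y0 + radius * np.cos(t), radius * np.sin(t)], axis=1
    )
    outward = np.stack([np.zeros(n), np.cos(t), np.sin(t)], axis=1)
    cb = ca + _SIDECHAIN_LEN * outward
    return ca, cb


def _block(n: int, width: int) -> np.ndarray:
    """Snake-packed 3D block: width × width layers stacked in z."""
    per_layer = width * width
    layer, rem = divmod(np.arange(n), per_layer)
    row, col = divmod(rem, width)
    x = np.where(row % 2 == 0, col, width - 1 - col)
    y = np.where(layer % 2 == 0, row, width - 1 - row)
    return np.stack([x, y, layer], axis=1) * _CA_SPACING


def _patch(n: int, width: int) -> np.ndarray:
    """Flat boustrophedon grid in a z-plane."""
    row, col = divmod(np.arange(n), width)
    x = np.where(row % 2 == 0, col, width - 1 - col)
    return np.stack([x, row, np.zeros(n, dtype=int)], axis=1) * _CA_SPACING


# In-plane jitter (Å, uniform per x/y coordinate) on the host chain breaks
# the lattice's translational mode degeneracy so fast modes localize the way
# they do in irregular folded chains.  The docked patch and the z coordinates
# stay exact: every interchain atom-pair family then sits a safe margin
# inside or outside the 4.5 Å contact cutoff, which makes the native pose
# contact-maximal under any near-native move (there is no steric term to
# forbid interpenetrating poses otherwise).
_JITTER = 0.15


def _grid_patch_traces(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    ca_a = _block(spec.n_a, spec.grid_width)
    # host CB alternates ±x within the block
    dx = _SIDECHAIN_LEN * np.where(np.arange(spec.n_a) % 2 == 0, 1.0, -1.0)
    cb_off_a = np.stack([dx, np.zeros(spec.n_a), np.zeros(spec.n_a)], axis=1)
    top_z = ca_a[:, 2].max()
    ca_b = _patch(spec.n_b, spec.grid_width)
    # centre the patch over the top face, at interface_gap above it
    ca_b = ca_b.astype(float)
    # centre the patch over the top face, snapped to the lattice so patch
    # nodes sit exactly above host nodes (keeps all non-contact pairs a full
    # lattice step away from the contact cutoff)
    offset = ca_a[:, :2].mean(axis=0) - ca_b[:, :2].mean(axis=0)
    ca_b[:, :2] += np.round(offset / _CA_SPACING) * _CA_SPACING
    ca_b[:, 2] = top_z + spec.interface_gap
    # patch CB alternates toward/away from the host face
    dz = _SIDECHAIN_LEN * np.where(np.arange(spec.n_b) % 2 == 0, -1.0, 1.0)
    cb_off_b = np.stack([np.zeros(spec.n_b), np.zeros(spec.n_b), dz], axis=1)
    jit_a = rng.uniform(-_JITTER, _JITTER, ca_a.shape)
    jit_a[:, 2] = 0.0
    ca_a = ca_a + jit_a
    return ca_a, ca_a + cb_off_a, ca_b, ca_b + cb_off_b


def make_toy_dimer(spec: FixtureSpec) -> ToyDimer:
    """Build a two-chain toy complex from the requested geometry.

    For ``strand_pair`` the analytically known contact sets are returned;
    for the other geometries they are None (no simple closed form).
    """
    if spec.geometry == "strand_pair":
        ca_a, cb_a = _strand(spec.n_a, 0.0, cb_sign=1.0)
        ca_b, cb_b = _strand(spec.n_b, spec.interface_gap, cb_sign=1.0)
        exp_a, exp_b = _strand_pair_contacts(spec)
    elif spec.geometry == "helix_pair":
        ca_a, cb_a = _helix(spec.n_a, 0.0)
        ca_b, cb_b = _helix(spec.n_b, 2 * 2.3 + spec.interface_gap)
        exp_a = exp_b = None
    else:  # grid_patch
        ca_a, cb_a, ca_b, cb_b = _grid_patch_traces(spec)
        exp_a = exp_b = None
    chain_a = _chain_from_traces("A", ca_a, cb_a, aa_offset=0)
    chain_b = _chain_from_traces("B", ca_b, cb_b, aa_offset=5)
    dimer = DimerModel(chain_a=chain_a, chain_b=chain_b, source=f"synthetic:{spec.geometry}")
    return ToyDimer(dimer=dimer, expected_contacts_a=exp_a, expected_contacts_b=exp_b)


def _strand_pair_contacts(spec: FixtureSpec) -> tuple[set[int], set[int]]:
    """Closed-form contact sets of the facing-strand geometry.

    With both strands' CB alternating ±z in phase, the minimum interatomic
    distance between residues i (chain A) and j (chain B) is
    sqrt((3.8·|i−j|)² + gap²), so residue pairs are contacts iff that is
    ≤ the 4.5 Å cutoff.
    """
    g = spec.interface_gap
    if g > CONTACT_CUTOFF:
        return set(), set()
    reach = int(np.floor(np.sqrt(CONTACT_CUTOFF ** 2 - g ** 2) / _CA_SPACING))
    contacts_a = {
        i for i in range(spec.n_a)
        if any(0 <= i + d < spec.n_b for d in range(-reach, reach + 1))
    }
    contacts_b = {
        j for j in range(spec.n_b)
        if any(0 <= j + d < spec.n_a for d in range(-reach, reach + 1))
    }
    return contacts_a, contacts_b


def _transform_chain(chain: ChainModel, rot: np.ndarray, shift: np.ndarray) -> ChainModel:
    """Rigid transform about the chain's Cα centroid, then translate."""
    center = chain.ca_array().mean(axis=0)
    out = ChainModel(chain_id=chain.chain_id)
    for res in chain.residues:
        new = ResidueModel(seq_index=res.seq_index, author_id=res.author_id, aa_type=res.aa_type)
        for atom in res.atoms:
            coord = (atom.coord - center) @ rot.T + center + shift
            new.atoms.append(
                AtomRecord(
                    name=atom.name, element=atom.element, coord=coord,
                    occupancy=atom.occupancy, altloc=atom.altloc,
                )
            )
        out.residues.append(new)
    return out


def _bounding_radius(chain: ChainModel) -> float:
    ca = chain.ca_array()
    center = ca.mean(axis=0)
    return float(np.linalg.norm(ca - center, axis=1).max())


def make_decoy_set(spec: FixtureSpec) -> tuple[list[tuple[str, DimerModel]], dict[str, str]]:
    """Generate a rigid-body decoy set with labels.

    Decoy 0 is the unperturbed native.  The next ``near_native_count − 1``
    decoys slide/twist chain B in the docking plane by at most
    ``perturbation_scale`` (Å / degrees).  The rest are far poses: chain B is
    rotated arbitrarily and placed at a random direction well outside contact
    range, so far decoys have no interchain contacts.

    Returns the (id, dimer) list and an id → flag label mapping.
    """
    if spec.decoy_count < 2:
        raise ValueError("decoy_count must be at least 2")
    if spec.perturbation_scale <= 0:
        raise ValueError("perturbation_scale must be positive")
    if not 1 <= spec.near_native_count < spec.decoy_count:
        raise ValueError("near_native_count must be in [1, decoy_count)")
    rng = np.random.default_rng(spec.seed)
    native = make_toy_dimer(spec).dimer
    width = len(str(spec.decoy_count - 1))
    decoys: list[tuple[str, DimerModel]] = []
    labels: dict[str, str] = {}

    def _add(idx: int, dimer: DimerModel, flag: str) -> None:
        did = f"decoy_{idx:0{width}d}"
        decoys.append((did, dimer))
        labels[did] = flag

    _add(0, native, "native")
    # docking-plane axes: normal is z for grid_patch, y otherwise
    normal = np.array([0.0, 0.0, 1.0]) if spec.geometry == "grid_patch" else np.array([0.0, 1.0, 0.0])
    plane = [v for v in np.eye(3) if abs(v @ normal) < 0.5]
    for k in range(1, spec.near_native_count):
        angle = rng.uniform(-spec.perturbation_scale, spec.perturbation_scale)
        rot = Rotation.from_rotvec(np.deg2rad(angle) * normal).as_matrix()
        t = rng.uniform(-1.0, 1.0, size=2)
        t *= spec.perturbation_scale * rng.uniform(0, 1) / max(np.linalg.norm(t), 1e-12)
        shift = t[0] * plane[0] + t[1] * plane[1]
        chain_b = _transform_chain(native.chain_b, rot, shift)
        _add(k, DimerModel(native.chain_a, chain_b, source=f"{native.source}:near{k}"), "near_native")
    r_a = _bounding_radius(native.chain_a)
    r_b = _bounding_radius(native.chain_b)
    center_a = native.chain_a.ca_array().mean(axis=0)
    center_b = native.chain_b.ca_array().mean(axis=0)
    for k in range(spec.near_native_count, spec.decoy_count):
        rot = Rotation.random(random_state=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        distance = r_a + r_b + rng.uniform(20.0, 50.0)
        shift = center_a + distance * direction - center_b
        chain_b = _transform_chain(native.chain_b, rot, shift)
        _add(k, DimerModel(native.chain_a, chain_b, source=f"{native.source}:far{k}"), "far")
    return decoys, labels


def _dimer_to_atom_array(dimer: DimerModel) -> struc.AtomArray:
    records = []
    for chain in (dimer.chain_a, dimer.chain_b):
        for res in chain.residues:
            for atom in res.atoms:
                records.append((chain.chain_id, res.seq_index + 1, res.aa_type, atom))
    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r[3].coord for r in records])
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3].name for r in records])
    arr.element = np.array([r[3].element for r in records])
    arr.hetero = np.zeros(len(records), dtype=bool)
    arr.set_annotation("occupancy", np.ones(len(records)))
    return arr


def write_dimer_pdb(dimer: DimerModel, path: str | Path) -> None:
    """Write the dimer as a standard PDB file (coordinates to 1e-3 Å)."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_dimer_to_atom_array(dimer))
    pdb_file.write(str(path))


def write_decoy_set(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write one PDB per decoy plus a ``labels.txt`` file; returns the label path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    decoys, labels = make_decoy_set(spec)
    for did, dimer in decoys:
        write_dimer_pdb(dimer, out_dir / f"{did}.pdb")
    label_path = out_dir / "labels.txt"
    with open(label_path, "w") as fh:
        fh.write(f"# synthetic decoy set seed={spec.seed} geometry={spec.geometry}\n")
        for did, flag in labels.items():
            fh.write(f"{did} {flag}\n")
    return label_path
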