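import numpy as np
import pytest

from gnmscaffold.structure_io import AtomRecord, ChainModel, DimerModel, ResidueModel
from gnmscaffold.synthetic_fixtures import FixtureSpec, make_toy_dimer

CA_SPACING = 3.8


def chain_from_ca(
    coords,
    chain_id="A",
    cb_offsets=None,
    missing=(),
    aa_types=None,
):
    """Build a ChainModel from raw Cα coordinates.

    ``missing`` lists seq indices that get a residue slot but no atoms
    (unresolved residues); ``cb_offsets`` optionally adds one pseudo
    side-chain atom per residue.
    """
    coords = np.asarray(coords, dtype=float)
    chain = ChainModel(chain_id=chain_id)
    for i in range(len(coords)):
        aa = aa_types[i] if aa_types else "ALA"
        res = ResidueModel(seq_index=i, author_id=str(i + 1), aa_type=aa)
        if i not in missing:
            res.atoms.append(AtomRecord(name="CA", element="C", coord=coords[i]))
            if cb_offsets is not None:
                res.atoms.append(
                    AtomRecord(name="CB", element="C", coord=coords[i] + cb_offsets[i])
                )
        chain.residues.append(res)
    return chain


def straight_chain(n, chain_id="A", spacing=CA_SPACING, missing=()):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return chain_from_ca(coords, chain_id=chain_id, missing=missing)


def random_walk_chain(n, rng, chain_id="A", origin=(0.0, 0.0, 0.0)):
    """Random 3.8 Å-step walk with random 1.5 Å pseudo side chains."""
    steps = rng.normal(size=(n - 1, 3))
    steps = CA_SPACING * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + np.asarray(origin)
    cb = rng.normal(size=(n, 3))
    cb = 1.5 * cb / np.linalg.norm(cb, axis=1, keepdims=True)
    return chain_from_ca(coords, chain_id=chain_id, cb_offsets=cb)


def random_dimer(rng, n_a=None, n_b=None):
    """Two random-walk chains placed close enough to share an interface."""
    n_a = n_a or int(rng.integers(12, 60))
    n_b = n_b or int(rng.integers(12, 60))
    chain_a = random_walk_chain(n_a, rng, "A")
    offset = rng.normal(size=3)
    offset = rng.uniform(3.0, 8.0) * offset / np.linalg.norm(offset)
    chain_b = random_walk_chain(n_b, rng, "B", origin=offset)
    return DimerModel(chain_a, chain_b, source="random")


@pytest.fixture
def strand_dimer():
    return make_toy_dimer(
        FixtureSpec(n_a=40, n_b=40, geometry="strand_pair", interface_gap=4.0, seed=7)
    )


@pytest.fixture
def grid_dimer():
    return make_toy_dimer(FixtureSpec(seed=11)).dimer
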