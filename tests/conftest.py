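import numpy as np
import pytest

from em3p2 import MolecularGraph, Molecule, PropertyTask


def random_graph(rng: np.random.Generator, n_atoms: int, atom_vocab=(8, 3)) -> MolecularGraph:
    """Random connected attributed graph (tree plus a couple of extra edges)."""
    atoms = np.stack(
        [rng.integers(0, v, size=n_atoms) for v in atom_vocab], axis=1
    )
    src, dst = [], []
    for v in range(1, n_atoms):
        u = int(rng.integers(0, v))
        src += [v, u]
        dst += [u, v]
    for _ in range(int(rng.integers(0, 3))):
        if n_atoms >= 2:
            i, j = rng.choice(n_atoms, size=2, replace=False)
            src += [int(i), int(j)]
            dst += [int(j), int(i)]
    bond_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    bond_codes = np.zeros((bond_index.shape[1], 1), dtype=np.int64)
    return MolecularGraph(atoms, bond_index, bond_codes)


def toy_task(rng: np.random.Generator, n_members=40, pos_fraction=0.5, task_id="toy") -> PropertyTask:
    members = []
    for i in range(n_members):
        g = random_graph(rng, int(rng.integers(5, 12)))
        y = int(rng.random() < pos_fraction)
        members.append((Molecule(key=f"{task_id}-{i}", graph=g), y))
    return PropertyTask(task_id=task_id, members=members)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
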