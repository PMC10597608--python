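"""Molecular graphs, multi-task label tables and few-shot episode sampling.

Molecules are attributed undirected graphs.  Each atom carries a small tuple
of categorical feature codes (by default: atomic-number code and chirality
tag), each bond a tuple of categorical bond codes (bond-type and
bond-direction).  A chemical bond is stored as two directed entries so that
message passing can index neighbours with a flat edge list.

Property tasks follow the MoleculeNet dialect: one CSV with a SMILES column
plus one binary-label column per task, blank cells meaning "unlabeled for
this task".  Rows are dropped per task, never globally, so tasks over the
same molecule universe generally have different member counts.

Episodes are the unit of few-shot learning: N support molecules for
adaptation plus M query molecules for evaluation, with optional class
balancing of the query set (exactly M/C per class).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    """A SMILES string (or fixture record) could not be parsed."""


class ConfigurationError(ValueError):
    """Invalid configuration: missing columns, bad field values, ..."""


class DataError(ValueError):
    """Data violates a contract (single-class labels, insufficient tasks, ...)."""


class BalancedSamplingError(DataError):
    """A class was exhausted while balanced-sampling a query set."""

    def __init__(self, task_id: str, label: int, needed: int, available: int):
        self.task_id = task_id
        self.label = label
        super().__init__(
            f"task {task_id!r}: class {label} has {available} molecules left in "
            f"the query pool but balanced sampling needs {needed}"
        )


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------


@dataclass
class MolecularGraph:
    """Attributed undirected graph of atoms and bonds.

    atom_codes : (n_atoms, n_atom_features) integer array
    bond_index : (2, n_directed) integer array; every chemical bond appears
                 in both directions, no self loops
    bond_codes : (n_directed, n_bond_features) integer array
    """

    atom_codes: np.ndarray
    bond_index: np.ndarray
    bond_codes: np.ndarray

    def __post_init__(self) -> None:
        self.atom_codes = np.asarray(self.atom_codes, dtype=np.int64)
        if self.atom_codes.ndim != 2 or self.atom_codes.shape[0] < 1:
            raise ValueError("atom_codes must be (n_atoms >= 1, n_features)")
        self.bond_index = np.asarray(self.bond_index, dtype=np.int64).reshape(2, -1)
        self.bond_codes = np.asarray(self.bond_codes, dtype=np.int64)
        if self.bond_codes.ndim == 1:
            self.bond_codes = self.bond_codes.reshape(self.bond_index.shape[1], -1)
        n, m = self.n_atoms, self.bond_index.shape[1]
        if m:
            if self.bond_index.min() < 0 or self.bond_index.max() >= n:
                raise ValueError("bond endpoint out of range")
            if np.any(self.bond_index[0] == self.bond_index[1]):
                raise ValueError("self loops are not allowed")

    @property
    def n_atoms(self) -> int:
        return self.atom_codes.shape[0]

    @property
    def n_bonds(self) -> int:
        """Number of undirected bonds (directed entries / 2)."""
        return self.bond_index.shape[1] // 2

    def undirected_edge_set(self) -> set[tuple[int, int]]:
        return {
            (min(i, j), max(i, j))
            for i, j in zip(self.bond_index[0].tolist(), self.bond_index[1].tolist())
        }

    def __eq__(self, other: object) -> bool:  # structural equality for round-trips
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        if self.atom_codes.shape != other.atom_codes.shape:
            return False
        if not np.array_equal(self.atom_codes, other.atom_codes):
            return False
        # compare directed edges as a sorted multiset with their codes
        def canon(g: MolecularGraph):
            rows = np.concatenate([g.bond_index.T, g.bond_codes], axis=1)
            return rows[np.lexsort(rows.T[::-1])]

        a, b = canon(self), canon(other)
        return a.shape == b.shape and np.array_equal(a, b)


@dataclass(frozen=True)
class Molecule:
    """A molecule with a stable identity key (canonical SMILES or synthetic id)."""

    key: str
    graph: MolecularGraph
    smiles: Optional[str] = None


@dataclass
class PropertyTask:
    """One binary property-prediction task: (molecule, label) members."""

    task_id: str
    members: list[tuple[Molecule, int]]

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {0: 0, 1: 0}
        for _, y in self.members:
            counts[int(y)] = counts.get(int(y), 0) + 1
        return counts


@dataclass
class TaskCollection:
    tasks: list[PropertyTask]
    # task_id -> "meta_train" | "meta_test"; tasks absent from the map are unassigned
    split: dict[str, str] = field(default_factory=dict)

    def by_id(self, task_id: str) -> PropertyTask:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)

    def train_tasks(self) -> list[PropertyTask]:
        return [t for t in self.tasks if self.split.get(t.task_id) == "meta_train"]

    def test_tasks(self) -> list[PropertyTask]:
        return [t for t in self.tasks if self.split.get(t.task_id) == "meta_test"]


@dataclass
class Episode:
    """One few-shot instance: a support set for adaptation, a query set for evaluation."""

    task_id: str
    support: list[tuple[Molecule, int]]
    query: list[tuple[Molecule, int]]
    n_shot: int
    m_query: int
    n_classes: int = 2

    def __post_init__(self) -> None:
        s_keys = {m.key for m, _ in self.support}
        q_keys = {m.key for m, _ in self.query}
        if s_keys & q_keys:
            raise DataError(f"support and query overlap in episode for {self.task_id}")


# ---------------------------------------------------------------------------
# SMILES featurization (rdkit behind the scenes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeaturizerConfig:
    """Sizes of the categorical vocabularies for atom and bond features."""

    atom_vocab: tuple[int, ...] = (119, 4)  # atomic-number code, chirality tag
    bond_vocab: tuple[int, ...] = (4, 3)  # bond-type code, bond-direction tag


CHEMISTRY_FEATURIZER = FeaturizerConfig()

_BOND_TYPE_CODES = {"SINGLE": 0, "DOUBLE": 1, "TRIPLE": 2, "AROMATIC": 3}
_BOND_DIR_CODES = {"NONE": 0, "ENDUPRIGHT": 1, "ENDDOWNRIGHT": 2}


def smiles_to_graph(
    smiles: str, featurizer_config: FeaturizerConfig = CHEMISTRY_FEATURIZER
) -> MolecularGraph:
    """Parse a SMILES string into an attributed heavy-atom graph.

    Atom features: (atomic number - 1, chirality tag code); bond features:
    (bond-type code, bond-direction code).  Raises :class:`ParseError` naming
    the offending string on unparseable input.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"SMILES has no heavy atoms: {smiles!r}")

    v0, v1 = featurizer_config.atom_vocab
    atoms = np.zeros((mol.GetNumAtoms(), 2), dtype=np.int64)
    for a in mol.GetAtoms():
        atoms[a.GetIdx(), 0] = min(a.GetAtomicNum() - 1, v0 - 1)
        atoms[a.GetIdx(), 1] = min(int(a.GetChiralTag()), v1 - 1)

    src, dst, codes = [], [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bt = _BOND_TYPE_CODES.get(str(b.GetBondType()), 0)
        bd = _BOND_DIR_CODES.get(str(b.GetBondDir()), 0)
        src += [i, j]
        dst += [j, i]
        codes += [[bt, bd], [bt, bd]]
    bond_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    bond_codes = np.array(codes, dtype=np.int64).reshape(-1, 2)
    return MolecularGraph(atoms, bond_index, bond_codes)


def canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# MoleculeNet-dialect CSV loading
# ---------------------------------------------------------------------------


def load_moleculenet_csv(
    path,
    smiles_column: str = "smiles",
    task_columns: Optional[Sequence[str]] = None,
    featurizer_config: FeaturizerConfig = CHEMISTRY_FEATURIZER,
) -> TaskCollection:
    """Read a multi-task CSV into one :class:`PropertyTask` per label column.

    Blank/NaN cells drop the row from that task only.  Molecules that fail to
    parse are logged and skipped (the per-string parser raises; the batch
    loader degrades gracefully).
    """
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ConfigurationError(f"missing SMILES column {smiles_column!r} in {path}")
    if task_columns is None:
        task_columns = [c for c in df.columns if c != smiles_column]
    for c in task_columns:
        if c not in df.columns:
            raise ConfigurationError(f"missing task column {c!r} in {path}")

    molecules: list[Optional[Molecule]] = []
    for s in df[smiles_column].astype(str):
        try:
            key = canonical_smiles(s)
            molecules.append(Molecule(key=key, graph=smiles_to_graph(s, featurizer_config), smiles=s))
        except ParseError as exc:
            logger.warning("skipping molecule: %s", exc)
            molecules.append(None)

    tasks = []
    for c in task_columns:
        members: list[tuple[Molecule, int]] = []
        for mol, raw in zip(molecules, df[c]):
            if mol is None or pd.isna(raw):
                continue
            y = float(raw)
            if y not in (0.0, 1.0):
                raise DataError(f"task {c!r}: label {raw!r} is not binary")
            members.append((mol, int(y)))
        if not members:
            logger.warning("task %r has zero labeled rows; flagged empty", c)
        tasks.append(PropertyTask(task_id=str(c), members=members))
    return TaskCollection(tasks=tasks)


# ---------------------------------------------------------------------------
# meta-train / meta-test split
# ---------------------------------------------------------------------------


def split_tasks(
    collection: TaskCollection, n_train: int, n_test: int, seed: int
) -> TaskCollection:
    """Randomly assign ``n_train``/``n_test`` tasks to meta-train/meta-test.

    Deterministic given ``seed``; the two splits are disjoint.
    """
    ids = [t.task_id for t in collection.tasks]
    if n_train + n_test > len(ids):
        raise DataError(
            f"cannot split {len(ids)} tasks into {n_train} train + {n_test} test"
        )
    order = np.random.default_rng(seed).permutation(len(ids))
    split: dict[str, str] = {}
    for k in order[:n_train]:
        split[ids[int(k)]] = "meta_train"
    for k in order[n_train : n_train + n_test]:
        split[ids[int(k)]] = "meta_test"
    return TaskCollection(tasks=collection.tasks, split=split)


# ---------------------------------------------------------------------------
# episode sampling
# ---------------------------------------------------------------------------


def sample_episode(
    task: PropertyTask,
    n_shot: int,
    m_query: int,
    balanced: bool,
    rng: np.random.Generator,
    n_classes: int = 2,
    support_per_class: bool = False,
    replacement_fallback: bool = False,
) -> Episode:
    """Sample one few-shot episode from a task.

    Support is drawn uniformly without replacement (``support_per_class=True``
    switches to N per class).  The query set is disjoint from the support; with
    ``balanced=True`` exactly ``m_query / n_classes`` members are drawn per
    class, which is the query-balancing step that protects the meta-update
    from majority-class collapse.
    """
    if balanced and m_query % n_classes:
        raise ConfigurationError(
            f"m_query={m_query} must be divisible by n_classes={n_classes} "
            "for balanced query sampling"
        )
    members = list(task.members)
    if not members:
        raise DataError(f"task {task.task_id!r} is empty")
    idx = np.arange(len(members))

    if support_per_class:
        support_idx: list[int] = []
        for c in range(n_classes):
            pool_c = idx[[members[i][1] == c for i in idx]]
            if len(pool_c) < n_shot:
                raise DataError(
                    f"task {task.task_id!r}: class {c} has only {len(pool_c)} "
                    f"members, cannot draw {n_shot} per-class support"
                )
            support_idx += list(rng.choice(pool_c, size=n_shot, replace=False))
        support_idx = list(np.array(support_idx))
    else:
        if len(members) < n_shot:
            raise DataError(
                f"task {task.task_id!r} has {len(members)} members < n_shot={n_shot}"
            )
        support_idx = list(rng.choice(idx, size=n_shot, replace=False))

    support_set = set(int(i) for i in support_idx)
    pool = [i for i in idx if int(i) not in support_set]

    if balanced:
        per_class = m_query // n_classes
        query_idx: list[int] = []
        for c in range(n_classes):
            pool_c = [i for i in pool if members[i][1] == c]
            if len(pool_c) < per_class:
                if replacement_fallback and pool_c:
                    logger.warning(
                        "task %r: class %d exhausted (%d < %d); sampling with replacement",
                        task.task_id, c, len(pool_c), per_class,
                    )
                    query_idx += list(rng.choice(pool_c, size=per_class, replace=True))
                else:
                    raise BalancedSamplingError(task.task_id, c, per_class, len(pool_c))
            else:
                query_idx += list(rng.choice(pool_c, size=per_class, replace=False))
        query_idx = list(rng.permutation(np.array(query_idx)))
    else:
        if len(pool) < m_query:
            raise DataError(
                f"task {task.task_id!r}: query pool has {len(pool)} < m_query={m_query}"
            )
        query_idx = list(rng.choice(np.array(pool), size=m_query, replace=False))

    support = [members[int(i)] for i in support_idx]
    query = [members[int(i)] for i in query_idx]
    return Episode(
        task_id=task.task_id,
        support=support,
        query=query,
        n_shot=n_shot,
        m_query=m_query,
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# JSON-lines fixture format: one record per molecule
# ---------------------------------------------------------------------------


def _graph_to_record(g: MolecularGraph) -> dict:
    return {
        "atoms": g.atom_codes.tolist(),
        "bonds": [
            [int(i), int(j), [int(c) for c in code]]
            for i, j, code in zip(g.bond_index[0], g.bond_index[1], g.bond_codes)
        ],
    }


def _graph_from_record(rec: dict) -> MolecularGraph:
    atoms = np.array(rec["atoms"], dtype=np.int64).reshape(len(rec["atoms"]), -1)
    bonds = rec.get("bonds", [])
    if bonds:
        src = [b[0] for b in bonds]
        dst = [b[1] for b in bonds]
        codes = [b[2] for b in bonds]
    else:
        src, dst, codes = [], [], []
    bond_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    n_bf = len(codes[0]) if codes else 1
    bond_codes = np.array(codes, dtype=np.int64).reshape(-1, n_bf)
    return MolecularGraph(atoms, bond_index, bond_codes)


def write_jsonl(collection: TaskCollection, path) -> None:
    """Write a collection as JSON-lines: {key, smiles?, atoms, bonds, labels}."""
    universe: dict[str, Molecule] = {}
    labels: dict[str, dict[str, int]] = {}
    for t in collection.tasks:
        for mol, y in t.members:
            universe[mol.key] = mol
            labels.setdefault(mol.key, {})[t.task_id] = int(y)
    task_ids = [t.task_id for t in collection.tasks]
    with open(path, "w") as fh:
        fh.write(json.dumps({"_tasks": task_ids, "_split": collection.split}) + "\n")
        for key, mol in universe.items():
            rec = {"key": key, "smiles": mol.smiles, "labels": labels.get(key, {})}
            rec.update(_graph_to_record(mol.graph))
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> TaskCollection:
    """Read the JSON-lines fixture format back into a :class:`TaskCollection`."""
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines or "_tasks" not in lines[0]:
        raise ParseError(f"{path}: not a task fixture (missing header record)")
    header, records = lines[0], lines[1:]
    molecules = {}
    for rec in records:
        molecules[rec["key"]] = (
            Molecule(key=rec["key"], graph=_graph_from_record(rec), smiles=rec.get("smiles")),
            rec.get("labels", {}),
        )
    tasks = []
    for tid in header["_tasks"]:
        members = [
            (mol, int(labs[tid])) for mol, labs in molecules.values() if tid in labs
        ]
        tasks.append(PropertyTask(task_id=tid, members=members))
    return TaskCollection(tasks=tasks, split=dict(header.get("_split") or {}))
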