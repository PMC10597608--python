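"""Synthetic few-shot graph-classification tasks with planted-motif labels.

The generator emulates the structure of few-shot molecular property suites: a
family of binary tasks over small attributed graphs, where a graph is positive
for task t exactly when it contains task t's structural motif as a subgraph
(before optional label noise).  Class imbalance is controlled directly
(``positive_fraction``), down to the extreme regimes seen in real screening
data (positive/negative label ratios around 0.002).

Default motifs are the cycles C3..C8.  Distinct cycle lengths are pairwise
incomparable under subgraph containment, so no task's positives are
accidentally positive for another.  A motif is planted by building the cycle
from fresh nodes and fusing it onto exactly one randomly chosen background
node: sharing a single vertex adds the motif cycle and nothing else, so the
label stays clean.  Total graph size is drawn from the same distribution for
both classes (positives use a correspondingly smaller background), so
positives are not separable by size.

Backgrounds are random recursive trees plus a few extra edges (connected,
molecule-like sparsity); negative backgrounds are rejection-sampled until they
do not contain the task's motif.  Because detecting an unattributed cycle is
at the edge of what a Weisfeiler-Lehman-bounded encoder can express, motif
nodes are biased toward a distinguished "reactive-center" atom code
(``motif_feature_bias``), shared across tasks by default: tasks are related
through a common feature+structure signature — the premise that makes
meta-learning across them meaningful, much as real toxicity tasks share
toxophore chemistry.  ``per_task_signal_code=True`` gives every task its own
code instead, which forces transfer to happen purely at the representation
level and makes held-out tasks much harder at desk scale.

Graphs are not chemically valid molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .data_io import (
    ConfigurationError,
    DataError,
    MolecularGraph,
    Molecule,
    PropertyTask,
    TaskCollection,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


def cycle_motif(k: int) -> nx.Graph:
    g = nx.cycle_graph(k)
    g.graph["name"] = f"C{k}"
    return g


def default_motif_library(n: int = 6) -> list[nx.Graph]:
    """Cycles C3..C(n+2): pairwise incomparable under subgraph containment."""
    return [cycle_motif(k) for k in range(3, 3 + n)]


def contains_motif(graph: nx.Graph, motif: nx.Graph) -> bool:
    """True when ``motif`` occurs in ``graph`` as a (not necessarily induced) subgraph."""
    matcher = nx.algorithms.isomorphism.GraphMatcher(graph, motif)
    return matcher.subgraph_is_monomorphic()


def molecular_graph_to_networkx(g: MolecularGraph) -> nx.Graph:
    out = nx.Graph()
    out.add_nodes_from(range(g.n_atoms))
    out.add_edges_from(zip(g.bond_index[0].tolist(), g.bond_index[1].tolist()))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTaskConfig:
    """Conditions for one synthetic task family.

    ``positive_fraction`` is the per-graph probability of a positive label, so
    realized counts are binomial.  ``label_noise`` flips each label
    independently and is the irreducible error floor reported by
    :func:`bayes_error_estimate`.
    """

    n_tasks: int = 6
    graphs_per_task: int = 300
    atom_count_range: tuple[int, int] = (10, 20)
    motif_library: Optional[Sequence[nx.Graph]] = None
    positive_fraction: float = 0.5
    label_noise: float = 0.0
    seed: int = 0
    atom_vocab: tuple[int, int] = (8, 3)
    motif_feature_bias: float = 0.9
    per_task_signal_code: bool = False
    extra_edge_rate: float = 1.0
    max_regenerate: int = 500

    def motifs(self) -> list[nx.Graph]:
        lib = list(self.motif_library) if self.motif_library is not None else default_motif_library()
        return [lib[t % len(lib)] for t in range(self.n_tasks)]

    def validate(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ConfigurationError("positive_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must be in [0, 0.5)")
        lo, hi = self.atom_count_range
        if lo < 3 or hi < lo:
            raise ConfigurationError("atom_count_range must satisfy 3 <= min <= max")
        for m in self.motifs():
            if m.number_of_nodes() > lo - 2:
                raise ConfigurationError(
                    f"motif {m.graph.get('name', '?')} has {m.number_of_nodes()} nodes; "
                    f"the minimum graph size {lo} leaves no room for a background"
                )


#: positive fractions mimicking the imbalance regimes of common benchmark suites
#: (positive/negative label ratios 0.08, 0.76 and 0.002 respectively)
IMBALANCE_PRESETS = {
    "tox21_like": 0.08 / 1.08,
    "sider_like": 0.76 / 1.76,
    "muv_like": 0.002 / 1.002,
}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_background(n: int, extra_edge_rate: float, rng: np.random.Generator) -> nx.Graph:
    """Random recursive tree plus a few extra edges: connected and sparse."""
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, int(rng.integers(0, v)))
    if n >= 2:
        for _ in range(int(rng.poisson(extra_edge_rate))):
            i, j = rng.choice(n, size=2, replace=False)
            g.add_edge(int(i), int(j))
    return g


def _finalize(
    g: nx.Graph,
    planted_nodes: list[int],
    signal_code: int,
    cfg: SyntheticTaskConfig,
    rng: np.random.Generator,
) -> MolecularGraph:
    n = g.number_of_nodes()
    feat0 = rng.integers(0, cfg.atom_vocab[0], size=n)
    feat1 = rng.integers(0, cfg.atom_vocab[1], size=n)
    for v in planted_nodes:
        if rng.random() < cfg.motif_feature_bias:
            feat0[v] = signal_code
    atoms = np.stack([feat0, feat1], axis=1)
    src, dst = [], []
    for i, j in g.edges():
        src += [i, j]
        dst += [j, i]
    bond_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    bond_codes = np.zeros((bond_index.shape[1], 1), dtype=np.int64)
    return MolecularGraph(atoms, bond_index, bond_codes)


def _positive_graph(
    n: int, motif: nx.Graph, cfg: SyntheticTaskConfig, rng: np.random.Generator
) -> tuple[nx.Graph, list[int]]:
    """Background on n-k+1 nodes with the k-node motif fused at one node."""
    k = motif.number_of_nodes()
    g = _random_background(n - k + 1, cfg.extra_edge_rate, rng)
    fuse = int(rng.integers(0, g.number_of_nodes()))
    fresh = list(range(g.number_of_nodes(), n))
    cycle_nodes = [fuse] + fresh
    order = list(motif.nodes())
    mapping = {order[i]: cycle_nodes[i] for i in range(k)}
    for a, b in motif.edges():
        g.add_edge(mapping[a], mapping[b])
    return g, cycle_nodes


def _negative_graph(
    n: int, motif: nx.Graph, cfg: SyntheticTaskConfig, rng: np.random.Generator
) -> nx.Graph:
    """Background on n nodes, rejection-sampled to exclude the motif."""
    for _ in range(cfg.max_regenerate):
        g = _random_background(n, cfg.extra_edge_rate, rng)
        if not contains_motif(g, motif):
            return g
    raise DataError(
        f"could not draw a motif-free background of size {n} in {cfg.max_regenerate} tries"
    )


def generate_tasks(config: SyntheticTaskConfig) -> TaskCollection:
    """Generate one :class:`PropertyTask` per motif; fully determined by ``config.seed``.

    Before noise, a graph is positive iff it contains the task's motif as a
    subgraph; both classes share one size distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    motifs = config.motifs()
    lo, hi = config.atom_count_range

    tasks = []
    for t, motif in enumerate(motifs):
        signal_code = t % config.atom_vocab[0] if config.per_task_signal_code else 0
        members: list[tuple[Molecule, int]] = []
        for i in range(config.graphs_per_task):
            positive = bool(rng.random() < config.positive_fraction)
            n = int(rng.integers(lo, hi + 1))
            if positive:
                g, planted = _positive_graph(n, motif, config, rng)
            else:
                g, planted = _negative_graph(n, motif, config, rng), []
            label = int(positive)
            if config.label_noise > 0 and rng.random() < config.label_noise:
                label = 1 - label
            mol = Molecule(
                key=f"synthetic-{config.seed}-t{t}-{i}",
                graph=_finalize(g, planted, signal_code, config, rng),
            )
            members.append((mol, label))
        name = motif.graph.get("name", f"m{t}")
        tasks.append(PropertyTask(task_id=f"task{t}-{name}", members=members))
    return TaskCollection(tasks=tasks)


def bayes_error_estimate(config: SyntheticTaskConfig) -> float:
    """Irreducible error when the motif is perfectly detectable: the label noise."""
    return float(config.label_noise)


def motif_oracle_accuracy(collection: TaskCollection, config: SyntheticTaskConfig) -> float:
    """Accuracy of the brute-force subgraph-isomorphism oracle over all tasks.

    With ``label_noise=0`` this is 1.0 by construction, which is what makes the
    generated problems a meaningful yardstick for a learned classifier.
    """
    motifs = config.motifs()
    correct = total = 0
    for t, task in enumerate(collection.tasks):
        for mol, y in task.members:
            pred = int(contains_motif(molecular_graph_to_networkx(mol.graph), motifs[t]))
            correct += int(pred == y)
            total += 1
    return correct / total if total else float("nan")
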