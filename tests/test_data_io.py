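"""Graph parsing, CSV loading, task splitting and episode sampling."""

import numpy as np
import pytest
from scipy.stats import chisquare

from em3p2 import (
    BalancedSamplingError,
    ConfigurationError,
    DataError,
    ParseError,
    TaskCollection,
    load_moleculenet_csv,
    read_jsonl,
    sample_episode,
    smiles_to_graph,
    split_tasks,
    write_jsonl,
)
from conftest import toy_task


class TestSmilesToGraph:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_bonds",
        [("C", 1, 0), ("CC", 2, 1), ("CCO", 3, 2), ("c1ccccc1", 6, 6)],
    )
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        g = smiles_to_graph(smiles)
        assert g.n_atoms == n_atoms
        assert g.n_bonds == n_bonds
        # every chemical bond is stored in both directions
        assert g.bond_index.shape[1] == 2 * n_bonds

    def test_benzene_matches_toolkit_enumeration(self):
        """Atom and bond features agree with an independent rdkit walk."""
        from rdkit import Chem

        g = smiles_to_graph("c1ccccc1")
        mol = Chem.MolFromSmiles("c1ccccc1")
        assert all(a.GetAtomicNum() == 6 for a in mol.GetAtoms())
        assert np.all(g.atom_codes[:, 0] == 5)  # carbon: atomic number 6 -> code 5
        expected_edges = {
            tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()
        }
        assert g.undirected_edge_set() == expected_edges
        assert np.all(g.bond_codes[:, 0] == 3)  # aromatic bond-type code

    def test_unparseable_smiles_raises_naming_string(self):
        with pytest.raises(ParseError, match="not-a-smiles"):
            smiles_to_graph("not-a-smiles")


class TestCsvLoading:
    def _write(self, tmp_path, text):
        p = tmp_path / "tasks.csv"
        p.write_text(text)
        return p

    def test_blank_cells_drop_rows_per_task(self, tmp_path):
        p = self._write(
            tmp_path,
            "smiles,taskA,taskB\nC,0,1\nCC,1,\nCCO,0,0\nCCC,1,1\n",
        )
        coll = load_moleculenet_csv(p)
        a = coll.by_id("taskA")
        b = coll.by_id("taskB")
        assert len(a.members) == 4
        assert len(b.members) == 3

    def test_all_blank_task_flagged_empty(self, tmp_path):
        p = self._write(tmp_path, "smiles,taskA,taskB\nC,0,\nCC,1,\n")
        coll = load_moleculenet_csv(p)
        assert coll.by_id("taskB").is_empty
        assert not coll.by_id("taskA").is_empty

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = self._write(tmp_path, "smiles,taskA\nC,0\n")
        with pytest.raises(ConfigurationError, match="taskX"):
            load_moleculenet_csv(p, task_columns=["taskX"])
        with pytest.raises(ConfigurationError, match="mol"):
            load_moleculenet_csv(p, smiles_column="mol")

    def test_nonbinary_label_rejected(self, tmp_path):
        p = self._write(tmp_path, "smiles,taskA\nC,2\n")
        with pytest.raises(DataError, match="binary"):
            load_moleculenet_csv(p)

    def test_twelve_task_layout(self, tmp_path):
        """A Tox21-shaped file (12 label columns) yields 12 tasks."""
        cols = ",".join(f"t{i}" for i in range(12))
        rows = "\n".join(f"{s},{','.join('1' if (r+i) % 2 else '0' for i in range(12))}"
                         for r, s in enumerate(["C", "CC", "CCO", "c1ccccc1"]))
        p = self._write(tmp_path, f"smiles,{cols}\n{rows}\n")
        coll = load_moleculenet_csv(p)
        assert len(coll.tasks) == 12
        assert all(len(t.members) == 4 for t in coll.tasks)


class TestSplitTasks:
    def _collection(self, rng, n):
        return TaskCollection(tasks=[toy_task(rng, 10, task_id=f"t{i}") for i in range(n)])

    @pytest.mark.parametrize("n_tasks,n_train,n_test", [(12, 9, 3), (27, 21, 6), (17, 12, 5)])
    def test_split_sizes_and_disjointness(self, rng, n_tasks, n_train, n_test):
        coll = split_tasks(self._collection(rng, n_tasks), n_train, n_test, seed=3)
        train = {t.task_id for t in coll.train_tasks()}
        test = {t.task_id for t in coll.test_tasks()}
        assert len(train) == n_train and len(test) == n_test
        assert not train & test

    def test_same_seed_same_assignment(self, rng):
        coll = self._collection(rng, 10)
        s1 = split_tasks(coll, 6, 3, seed=11).split
        s2 = split_tasks(coll, 6, 3, seed=11).split
        assert s1 == s2
        assert split_tasks(coll, 6, 3, seed=12).split != s1

    def test_insufficient_tasks(self, rng):
        with pytest.raises(DataError):
            split_tasks(self._collection(rng, 5), 4, 2, seed=0)


class TestSampleEpisode:
    def test_balanced_query_forced_counts(self, rng):
        task = toy_task(rng, n_members=108, pos_fraction=8 / 108)
        ep = sample_episode(task, n_shot=10, m_query=8, balanced=True, rng=rng)
        labels = [y for _, y in ep.query]
        assert labels.count(0) == 4 and labels.count(1) == 4

    def test_support_query_disjoint_many_draws(self, rng):
        task = toy_task(rng, n_members=60)
        for _ in range(50):
            ep = sample_episode(task, 10, 16, balanced=True, rng=rng)
            s = {m.key for m, _ in ep.support}
            q = {m.key for m, _ in ep.query}
            assert not s & q
            assert len(s) == 10 and len(q) == 16

    def test_balanced_every_episode_exact(self, rng):
        """Hard invariant: exactly M/C per class in every balanced episode."""
        task = toy_task(rng, n_members=80, pos_fraction=0.3)
        for _ in range(200):
            ep = sample_episode(task, 5, 8, balanced=True, rng=rng)
            labels = [y for _, y in ep.query]
            assert labels.count(0) == 4 and labels.count(1) == 4

    def test_unbalanced_query_tracks_pool_mix(self, rng):
        """Chi-square: random query draws match the pool's class proportions."""
        task = toy_task(rng, n_members=400, pos_fraction=0.1)
        pool_pos = sum(y for _, y in task.members) / len(task.members)
        counts = np.zeros(2)
        n_ep = 300
        for _ in range(n_ep):
            ep = sample_episode(task, 4, 20, balanced=False, rng=rng)
            for _, y in ep.query:
                counts[y] += 1
        total = counts.sum()
        expected = np.array([(1 - pool_pos) * total, pool_pos * total])
        assert chisquare(counts, expected).pvalue > 1e-3

    def test_class_exhaustion_names_task_and_class(self, rng):
        task = toy_task(rng, n_members=30, pos_fraction=0.02, task_id="rare")
        with pytest.raises(BalancedSamplingError, match="rare.*class 1"):
            sample_episode(task, 4, 20, balanced=True, rng=rng)

    def test_replacement_fallback(self, rng):
        task = toy_task(rng, n_members=30, pos_fraction=0.05, task_id="rare")
        n_pos = sum(y for _, y in task.members)
        assert 1 <= n_pos < 10
        ep = sample_episode(
            task, 2, 20, balanced=True, rng=rng, replacement_fallback=True
        )
        labels = [y for _, y in ep.query]
        assert labels.count(1) == 10

    def test_support_per_class_draws_n_per_class(self, rng):
        task = toy_task(rng, n_members=60, pos_fraction=0.4)
        ep = sample_episode(task, 3, 8, balanced=True, rng=rng, support_per_class=True)
        support_labels = [y for _, y in ep.support]
        assert support_labels.count(0) == 3 and support_labels.count(1) == 3

    def test_indivisible_m_query_rejected(self, rng):
        task = toy_task(rng, 40)
        with pytest.raises(ConfigurationError):
            sample_episode(task, 4, 7, balanced=True, rng=rng)

    def test_seeded_sampling_is_reproducible(self):
        task = toy_task(np.random.default_rng(0), 50)
        e1 = sample_episode(task, 6, 8, True, np.random.default_rng(42))
        e2 = sample_episode(task, 6, 8, True, np.random.default_rng(42))
        assert [m.key for m, _ in e1.support] == [m.key for m, _ in e2.support]
        assert [m.key for m, _ in e1.query] == [m.key for m, _ in e2.query]


class TestJsonlRoundTrip:
    def test_graphs_and_labels_survive(self, rng, tmp_path):
        tasks = [toy_task(rng, 15, task_id=f"t{i}") for i in range(3)]
        coll = TaskCollection(tasks=tasks, split={"t0": "meta_train", "t2": "meta_test"})
        path = tmp_path / "fixture.jsonl"
        write_jsonl(coll, path)
        back = read_jsonl(path)
        assert back.split == coll.split
        for t in tasks:
            bt = back.by_id(t.task_id)
            orig = {m.key: (m.graph, y) for m, y in t.members}
            assert set(orig) == {m.key for m, _ in bt.members}
            for m, y in bt.members:
                g0, y0 = orig[m.key]
                assert y == y0
                assert m.graph == g0  # atom codes, edge multiset and bond codes

    def test_not_a_fixture(self, tmp_path):
        p = tmp_path / "junk.jsonl"
        p.write_text('{"key": "x"}\n')
        with pytest.raises(ParseError):
            read_jsonl(p)
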