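"""SWC parsing, branch metrics and dendritic complexity."""

import numpy as np
import pandas as pd
import pytest

import v1sense as v
from v1sense.morpho import MorphologyTree


def two_primaries_tree():
    """Soma with two unbranched 50-µm dendrites."""
    return MorphologyTree(
        ids=[1, 2, 3],
        types=[1, 3, 3],
        xyz=[[0, 0, 0], [50, 0, 0], [-50, 0, 0]],
        radius=[5, 0.5, 0.5],
        parent=[-1, 1, 1],
    )


def bifurcating_tree():
    """One primary (10 µm) splitting into two 10-µm daughters."""
    return MorphologyTree(
        ids=[1, 2, 3, 4],
        types=[1, 3, 3, 3],
        xyz=[[0, 0, 0], [10, 0, 0], [20, 0, 0], [10, 10, 0]],
        radius=[5, 0.5, 0.5, 0.5],
        parent=[-1, 1, 2, 2],
    )


class TestReadWriteSwc:
    def test_minimal_two_node_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 40 0 0 0.5 1\n")
        m = v.branch_metrics(v.read_swc(p))
        assert m.n_primary == 1
        assert m.total_length == pytest.approx(40.0)

    def test_round_trip_preserves_topology(self, tmp_path):
        tree = v.make_morphology(seed=3)
        p = tmp_path / "t.swc"
        v.write_swc(tree, p)
        back = v.read_swc(p)
        np.testing.assert_array_equal(back.ids, tree.ids)
        np.testing.assert_array_equal(back.parent, tree.parent)
        assert v.analyze_tree(back).dc == pytest.approx(v.analyze_tree(tree).dc, rel=1e-6)

    def test_shuffled_lines_same_tree(self, tmp_path):
        tree = v.make_morphology(seed=4)
        p, q = tmp_path / "sorted.swc", tmp_path / "shuffled.swc"
        v.write_swc(tree, p)
        lines = p.read_text().strip().splitlines()
        rng = np.random.default_rng(0)
        rng.shuffle(lines)
        q.write_text("\n".join(lines) + "\n")
        a, b = v.analyze_tree(v.read_swc(p)), v.analyze_tree(v.read_swc(q))
        assert a.dc == pytest.approx(b.dc)
        assert a.n_nodes == b.n_nodes
        assert sorted(a.terminal_orders) == sorted(b.terminal_orders)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("1 1 0 0 0 5 -1\n1 3 1 0 0 1 1\n", "duplicate"),
            ("1 1 0 0 0 5 -1\n2 3 1 0 0 1 9\n", "orphan"),
            ("1 1 0 0 0 5 2\n2 3 1 0 0 1 1\n", "root|cycle"),
            ("1 1 0 0 0 5\n", ":1"),
            ("1 1 x 0 0 5 -1\n", ":1"),
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, content, match):
        p = tmp_path / "bad.swc"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            v.read_swc(p)


class TestBranchMetrics:
    def test_two_unbranched_primaries(self):
        m = v.branch_metrics(two_primaries_tree())
        assert (m.n_primary, m.n_nodes, m.n_ends) == (2, 0, 2)
        assert m.total_length == pytest.approx(100.0)
        assert list(m.terminal_orders) == [1, 1]

    def test_single_bifurcation(self):
        m = v.branch_metrics(bifurcating_tree())
        assert (m.n_primary, m.n_nodes, m.n_ends) == (1, 1, 2)
        assert m.total_length == pytest.approx(30.0)
        assert list(m.terminal_orders) == [2, 2]

    def test_axon_nodes_excluded(self):
        tree = MorphologyTree(
            ids=[1, 2, 3],
            types=[1, 3, 2],  # type 2 = axon
            xyz=[[0, 0, 0], [50, 0, 0], [0, 80, 0]],
            radius=[5, 0.5, 0.5],
            parent=[-1, 1, 1],
        )
        m = v.branch_metrics(tree)
        assert m.n_primary == 1
        assert m.total_length == pytest.approx(50.0)

    def test_random_trees_match_recursive_oracle(self):
        for seed in range(100):
            tree = v.make_morphology(branch_prob=0.5, seed=seed)
            m = v.branch_metrics(tree)
            oracle = _oracle_metrics(tree)
            assert m.n_primary == oracle["n_primary"]
            assert m.n_nodes == oracle["n_nodes"]
            assert m.n_ends == oracle["n_ends"]
            assert m.total_length == pytest.approx(oracle["total_length"])
            assert sorted(m.terminal_orders) == sorted(oracle["terminal_orders"])


class TestDendriticComplexity:
    def test_hand_values(self):
        assert v.analyze_tree(two_primaries_tree()).dc == pytest.approx(200.0)
        assert v.analyze_tree(bifurcating_tree()).dc == pytest.approx(180.0)

    def test_coordinate_scaling_doubles_dc(self):
        tree = v.make_morphology(seed=8)
        doubled = MorphologyTree(
            ids=tree.ids,
            types=tree.types,
            xyz=tree.xyz * 2.0,
            radius=tree.radius,
            parent=tree.parent,
        )
        assert v.analyze_tree(doubled).dc == pytest.approx(
            2 * v.analyze_tree(tree).dc, rel=1e-9
        )

    def test_reindexing_and_rigid_motion_invariance(self):
        tree = v.make_morphology(seed=12)
        # re-index ids by an offset-and-scramble map
        rng = np.random.default_rng(0)
        new_of = dict(zip(tree.ids.tolist(), (rng.permutation(len(tree.ids)) + 10).tolist()))
        theta = 0.5
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = MorphologyTree(
            ids=[new_of[int(i)] for i in tree.ids],
            types=tree.types,
            xyz=tree.xyz @ R.T + np.array([5.0, -3.0, 11.0]),
            radius=tree.radius,
            parent=[-1 if p == -1 else new_of[int(p)] for p in tree.parent],
        )
        assert v.analyze_tree(moved).dc == pytest.approx(v.analyze_tree(tree).dc, rel=1e-9)

    def test_no_primaries_rejected(self):
        m = v.MorphoMetrics(
            n_primary=0, n_nodes=0, n_ends=0, total_length=0.0, mean_length=0.0
        )
        with pytest.raises(ValueError):
            v.dendritic_complexity(m)


class TestNormalizeToReference:
    def test_reference_group_normalizes_to_one(self):
        trees = [v.make_morphology(seed=s) for s in range(6)]
        tab = v.metrics_table(trees)
        groups = np.array(["wt", "wt", "wt", "ko", "ko", "ko"])
        rel = v.normalize_to_reference(tab, groups=groups, reference_group="wt")
        np.testing.assert_allclose(rel[groups == "wt"].mean(), 1.0)

    def test_known_ratio(self):
        tab = pd.DataFrame({"total_length": [100.0, 138.0]})
        rel = v.normalize_to_reference(tab, reference_mean=pd.Series({"total_length": 100.0}))
        assert rel["total_length"].iloc[1] == pytest.approx(1.38)

    def test_rescaling_recovers_originals(self):
        tab = v.metrics_table([v.make_morphology(seed=s) for s in range(4)])
        ref = tab.mean()
        back = v.normalize_to_reference(tab, reference_mean=ref) * ref
        np.testing.assert_allclose(back.to_numpy(), tab.to_numpy())

    def test_zero_reference_rejected(self):
        tab = pd.DataFrame({"n_nodes": [0.0, 1.0]})
        with pytest.raises(ValueError, match="reference"):
            v.normalize_to_reference(tab, reference_mean=pd.Series({"n_nodes": 0.0}))


def _oracle_metrics(tree):
    """Independent recursive traversal (depth-first, explicit recursion)."""
    import sys

    idx = tree.index
    children = {int(i): [] for i in tree.ids}
    for i, p in zip(tree.ids, tree.parent):
        if p != -1:
            children[int(p)].append(int(i))
    dend = {int(i) for i, t in zip(tree.ids, tree.types) if t in (3, 4)}
    root = tree.root_id
    primaries = [c for c in children[root] if c in dend]
    out = {
        "n_primary": len(primaries),
        "n_nodes": 0,
        "n_ends": 0,
        "total_length": 0.0,
        "terminal_orders": [],
    }
    sys.setrecursionlimit(10000)

    def walk(nid, order):
        pid = int(tree.parent[idx[nid]])
        out["total_length"] += float(
            np.linalg.norm(tree.xyz[idx[nid]] - tree.xyz[idx[pid]])
        )
        kids = [c for c in children[nid] if c in dend]
        if not kids:
            out["n_ends"] += 1
            out["terminal_orders"].append(order)
        elif len(kids) == 1:
            walk(kids[0], order)
        else:
            out["n_nodes"] += 1
            for c in kids:
                walk(c, order + 1)

    for c in primaries:
        walk(c, 1)
    return out
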