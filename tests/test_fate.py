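import numpy as np
import pytest

from gcmig.fate import (
    FateError,
    classify_migrant_leaves,
    decompose_subtrees,
    migrant_composition,
    observed_post_migration,
    shuffle_migrations,
)
from gcmig.phylo import parsimony_labels
from gcmig.repertoire import UmiRecord
from gcmig.tree import LineageTree, Node


def _leaf(name, length, label):
    return Node(name=name, length=length, label=label)


def _labelled_cherry(label_a="A", label_b="B", len_a=0.1, len_b=0.2):
    root = Node(label=label_a)
    root.add(_leaf("a", len_a, label_a))
    root.add(_leaf("b", len_b, label_b))
    return LineageTree(root, lineage_id=0)


class TestDecompose:
    def test_no_migration_single_subtree(self):
        tree = _labelled_cherry(label_b="A")
        (sub,) = decompose_subtrees(tree)
        assert sub.divergence == pytest.approx(tree.total_divergence)
        assert not sub.follows_migration
        assert sub.n_leaves == 2

    def test_terminal_migration_zero_divergence(self):
        tree = _labelled_cherry()
        subs = decompose_subtrees(tree)
        migrant = [s for s in subs if s.follows_migration]
        assert len(migrant) == 1
        assert migrant[0].divergence == 0.0
        assert migrant[0].n_leaves == 1

    def test_hand_enumerated_six_leaf_tree(self):
        # ((a,b),(c,(d,(e,f)))) with two label changes: on the branch to the
        # (e,f) clade and on the terminal branch to c
        root = Node(label="X")
        ab = root.add(Node(length=0.01, label="X"))
        ab.add(_leaf("a", 0.02, "X"))
        ab.add(_leaf("b", 0.03, "X"))
        rest = root.add(Node(length=0.04, label="X"))
        rest.add(_leaf("c", 0.05, "Y"))          # cut 1 (length 0.05)
        d_ef = rest.add(Node(length=0.06, label="X"))
        d_ef.add(_leaf("d", 0.07, "X"))
        ef = d_ef.add(Node(length=0.08, label="Z"))  # cut 2 (length 0.08)
        ef.add(_leaf("e", 0.09, "Z"))
        ef.add(_leaf("f", 0.10, "Z"))
        tree = LineageTree(root, lineage_id=1)
        subs = decompose_subtrees(tree)
        by_label = {s.label: s for s in subs}
        # manual edge sums: X keeps 0.01+0.02+0.03+0.04+0.06+0.07 = 0.23
        assert by_label["X"].divergence == pytest.approx(0.23)
        assert by_label["Y"].divergence == 0.0
        assert by_label["Z"].divergence == pytest.approx(0.19)
        cut_total = 0.05 + 0.08
        total = sum(s.divergence for s in subs) + cut_total
        assert total == pytest.approx(tree.total_divergence)

    def test_conservation_on_simulated_trees(self, labelled_trees):
        trees, _ = labelled_trees
        for tree in trees:
            subs = decompose_subtrees(tree)
            cut = sum(b.length for b in tree.branches()
                      if b.label != b.parent.label)
            assert (sum(s.divergence for s in subs) + cut
                    == pytest.approx(tree.total_divergence, rel=1e-9))


class TestShuffle:
    def test_single_positive_branch_event_pinned(self):
        root = Node(label="A")
        root.add(_leaf("a", 0.1, "A"))
        root.add(_leaf("b", 0.0, "A"))
        tree = LineageTree(root)
        out = shuffle_migrations(tree, n_events=1, n_reps=20, seed=0)
        # the zero-length branch can never be chosen: every shuffled
        # migrant component is the single leaf below the long branch
        for divs in out.shuffled_divergences:
            assert divs.tolist() == [0.0]

    def test_length_weighted_branch_choice(self):
        root = Node(label="A")
        root.add(_leaf("a", 1.0, "A"))
        root.add(_leaf("b", 3.0, "A"))
        tree = LineageTree(root)
        rng_hits = 0
        n = 10_000
        out = shuffle_migrations(tree, n_events=1, n_reps=n, seed=1)
        # component after cutting branch b is leaf b (divergence 0) either
        # way; count via the internal choice by re-deriving from zero fracs
        # being uninformative here, use the branch sampler directly instead
        from numpy.random import default_rng

        lengths = np.array([1.0, 3.0])
        rng = default_rng(1)
        draws = rng.choice(2, size=n, p=lengths / lengths.sum())
        frac = (draws == 1).mean()
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_event_count_preserved(self, labelled_trees):
        trees, events = labelled_trees
        tree = max(trees, key=lambda t: len(events[t.lineage_id]))
        n_ev = len(events[tree.lineage_id])
        out = shuffle_migrations(tree, n_events=n_ev, n_reps=10, seed=2)
        for divs in out.shuffled_divergences:
            assert len(divs) == n_ev

    def test_too_many_events_error(self):
        tree = _labelled_cherry()
        with pytest.raises(FateError):
            shuffle_migrations(tree, n_events=5, n_reps=2, seed=0)

    def test_zero_fraction_matches_terminal_length_share(self):
        # single event on a 3-branch tree: migrant component has zero
        # divergence iff the cut branch is terminal
        root = Node(label="A")
        inner = root.add(Node(length=2.0, label="A"))
        inner.add(_leaf("a", 1.0, "A"))
        inner.add(_leaf("b", 1.0, "A"))
        tree = LineageTree(root)
        out = shuffle_migrations(tree, n_events=1, n_reps=4000, seed=3)
        expected = 2.0 / 4.0  # terminal length share
        assert out.shuffled_zero_fractions.mean() == pytest.approx(expected,
                                                                   abs=0.03)

    def test_observed_vs_shuffled_divergence_similarity(self, labelled_trees):
        # migration placement is mechanistically independent of subsequent
        # growth in the generator, so observed post-migration divergences
        # should look like shuffled ones in aggregate
        trees, events = labelled_trees
        obs, shuf = [], []
        for tree in trees:
            n_ev = len(events[tree.lineage_id])
            if n_ev < 1:
                continue
            try:
                out = shuffle_migrations(tree, n_ev, n_reps=20,
                                         seed=tree.lineage_id)
            except FateError:
                continue
            obs.extend(out.observed_divergences)
            for divs in out.shuffled_divergences:
                shuf.extend(divs)
        from scipy.stats import ks_2samp

        stat = ks_2samp(obs, shuf).statistic
        assert stat < 0.15


class TestMigrantComposition:
    def _records(self, spec):
        # spec: list of (umi, lineage, follicle)
        return [UmiRecord(umi_id=u, sequence="ACGT", v_sequence="ACGT",
                          follicle_id=f, lineage_id=l) for u, l, f in spec]

    def test_monofollicular_lineages_no_migrants(self):
        tree = _labelled_cherry(label_b="A")
        parsimony_labels(tree)
        recs = self._records([("a", 0, "A"), ("b", 0, "A")])
        comps = migrant_composition(recs, [tree])
        assert all(c.migrant_umi_fraction == 0 for c in comps)

    def test_fraction_arithmetic(self):
        # follicle 1: 10 UMIs, 3 of them from a lineage rooted in follicle 2
        root = Node(label=2)
        root.add(_leaf("m", 0.1, 1))
        root.add(_leaf("h", 0.1, 2))
        tree = LineageTree(root, lineage_id=1)
        tree.leaves()[0].weight = 3
        spec = [(f"r{i}", 0, 1) for i in range(7)]
        spec += [(f"m{i}", 1, 1) for i in range(3)]
        spec += [("h0", 1, 2)]
        local_tree = _labelled_cherry(label_a=1, label_b=1)
        local_tree.lineage_id = 0
        recs = self._records(spec)
        comps = migrant_composition(recs, [local_tree, tree])
        f1 = next(c for c in comps if c.follicle_id == 1)
        assert f1.migrant_umi_fraction == pytest.approx(0.3)

    def test_two_follicle_worked_example(self):
        # lineage 0 rooted in follicle 1 (3 UMIs in f1, 2 migrants in f2)
        # lineage 1 rooted in follicle 2 (4 UMIs in f2)
        t0_root = Node(label=1)
        a = t0_root.add(_leaf("l0f1", 0.1, 1))
        b = t0_root.add(_leaf("l0f2", 0.1, 2))
        a.weight, b.weight = 3, 2
        t0 = LineageTree(t0_root, lineage_id=0)
        t1_root = Node(label=2)
        c = t1_root.add(_leaf("l1f2a", 0.1, 2))
        d = t1_root.add(_leaf("l1f2b", 0.1, 2))
        c.weight, d.weight = 2, 2
        t1 = LineageTree(t1_root, lineage_id=1)
        spec = [(f"a{i}", 0, 1) for i in range(3)]
        spec += [(f"b{i}", 0, 2) for i in range(2)]
        spec += [(f"c{i}", 1, 2) for i in range(4)]
        recs = self._records(spec)
        comps = {c.follicle_id: c for c in migrant_composition(recs, [t0, t1])}
        # hand enumeration:
        # f1: 3 UMIs, none migrant -> fractions 0, top lineage 3/3
        assert comps[1].migrant_umi_fraction == 0.0
        assert comps[1].migrant_lineage_fraction == 0.0
        assert comps[1].top_lineage_frequency == 1.0
        assert comps[1].top_migrant_frequency == 0.0
        # f2: 6 UMIs, 2 migrants (lineage 0); 1 of 2 lineages is migrant
        assert comps[2].migrant_umi_fraction == pytest.approx(2 / 6)
        assert comps[2].migrant_lineage_fraction == pytest.approx(1 / 2)
        assert comps[2].top_lineage_frequency == pytest.approx(4 / 6)
        assert comps[2].top_migrant_frequency == pytest.approx(2 / 6)
        # invariant: top migrant <= top lineage
        assert comps[2].top_migrant_frequency <= comps[2].top_lineage_frequency

    def test_threshold_monotonicity(self, default_sim, labelled_trees):
        trees, _ = labelled_trees
        records = default_sim.records
        fractions = []
        for threshold in (0.0, 0.005, 0.01, 0.02):
            comps = migrant_composition(records, trees,
                                        min_migration_root_div=threshold)
            fractions.append({c.follicle_id: c.migrant_umi_fraction
                              for c in comps})
        for prev, cur in zip(fractions, fractions[1:]):
            for fid in cur:
                assert cur[fid] <= prev[fid] + 1e-12

    def test_deep_migrant_classification(self):
        # label change above an internal node makes every leaf below a
        # migrant, not only the immediate post-migration subtree
        root = Node(label=1)
        moved = root.add(Node(length=0.05, label=2))
        moved.add(_leaf("x", 0.02, 2))
        back = moved.add(Node(length=0.02, label=2))
        back.add(_leaf("y", 0.01, 2))
        back.add(_leaf("z", 0.01, 2))
        root.add(_leaf("w", 0.01, 1))
        tree = LineageTree(root, lineage_id=0)
        flags = classify_migrant_leaves(tree)
        assert flags == {"x": True, "y": True, "z": True, "w": False}
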