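"""NJ correctness (closed forms, additive recovery, reference agreement),
bootstrap supports, duplication-event counting."""

from __future__ import annotations

import io

import numpy as np
import pytest
import skbio

from youngdup.evometrics import CodonAlignment
from youngdup.simulate import mutate_cds, random_cds
from youngdup.trees import (
    FamilyTree,
    bipartitions,
    bootstrap,
    count_events,
    nj,
    p_distance_matrix,
)


def random_additive_tree(n: int, rng: np.random.Generator) -> skbio.TreeNode:
    """Random binary topology with uniform branch lengths (additive truth)."""
    labels = [f"t{i}" for i in range(n)]

    def build(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.05, 1.0):.6f}"
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        return f"({build(left)},{build(right)}):{rng.uniform(0.05, 1.0):.6f}"

    rng.shuffle(labels)
    return skbio.TreeNode.read(io.StringIO(build(labels) + ";"))


def tree_distances(tree: skbio.TreeNode) -> tuple[np.ndarray, list[str]]:
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    order = np.argsort(labels)
    mat = dm.data[np.ix_(order, order)]
    return mat, sorted(labels)


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        # a = (dAB + dAC - dBC)/2 etc.
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(np.zeros((2, 2)), ["A", "B"])

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj(d, list("ABC"))

    def test_quartet_split_recovered(self):
        # ((A,B),(C,D)) with internal edge 1.0
        d = np.array([
            [0.0, 3.0, 3.5, 4.5],
            [3.0, 0.0, 4.5, 5.5],
            [3.5, 4.5, 0.0, 4.0],
            [4.5, 5.5, 4.0, 0.0],
        ])
        tree = nj(d, list("ABCD"))
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_matrices_recover_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        truth = random_additive_tree(n, rng)
        d, labels = tree_distances(truth)
        ours = nj(d, labels)
        assert bipartitions(ours) == bipartitions(truth)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_reference_nj_implementation(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        truth = random_additive_tree(n, rng)
        d, labels = tree_distances(truth)
        ours = nj(d, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        assert bipartitions(ours) == bipartitions(ref)

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj(d, list("ABCD"))
        t2 = nj(d, list("ABCD"))
        assert str(t1) == str(t2)


class TestBootstrap:
    def _two_clade_alignment(self) -> CodonAlignment:
        base = random_cds(900, np.random.default_rng(0))
        far = mutate_cds(base, 0.35, 1)
        rows = {
            "a1": mutate_cds(base, 0.01, 2), "a2": mutate_cds(base, 0.01, 3),
            "a3": mutate_cds(base, 0.01, 4),
            "b1": mutate_cds(far, 0.01, 5), "b2": mutate_cds(far, 0.01, 6),
        }
        ids = sorted(rows)
        return CodonAlignment(ids, [rows[i] for i in ids])

    def test_separating_edge_support_high(self):
        aln = self._two_clade_alignment()
        ft = bootstrap(aln, "famX", n_reps=200, seed=0)
        sep = frozenset({"b1", "b2"})
        assert ft.supports[sep] >= 99.0

    def test_zero_replicates_no_supports(self):
        aln = self._two_clade_alignment()
        ft = bootstrap(aln, "famX", n_reps=0)
        assert ft.supports == {}

    def test_fixed_seed_reproducible(self):
        aln = self._two_clade_alignment()
        a = bootstrap(aln, "famX", n_reps=50, seed=7)
        b = bootstrap(aln, "famX", n_reps=50, seed=7)
        assert a.supports == b.supports

    def test_p_distance_pairwise_deletion(self):
        aln = CodonAlignment(["x", "y"], ["AAATTT", "AAA---"])
        d, labels = p_distance_matrix(aln)
        assert d[0, 1] == 0.0  # gapped half excluded


class TestCountEvents:
    def _family_tree(self, newick: str, supports: dict[frozenset, float]) -> FamilyTree:
        tree = skbio.TreeNode.read(io.StringIO(newick))
        return FamilyTree("famX", tree, supports, n_reps=100)

    SPECIES = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "c1": "C"}

    def test_supported_pair_clade_counted(self):
        ft = self._family_tree(
            "((a1:1,a2:1):1,(b1:1,c1:1):1,a3:1);",
            {frozenset({"a1", "a2"}): 80.0, frozenset({"b1", "c1"}): 40.0},
        )
        events = count_events(ft, self.SPECIES)
        assert len(events) == 1
        assert events[0].genes == {"a1", "a2"} and events[0].species == "A"

    def test_complement_side_counts_as_clade(self):
        # unrooted reading: the side {a1,a2,a3} opposite the supported
        # {b1,c1} edge is a single-species clade and absorbs the nested pair
        ft = self._family_tree(
            "((a1:1,a2:1):1,(b1:1,c1:1):1,a3:1);",
            {frozenset({"a1", "a2"}): 80.0, frozenset({"b1", "c1"}): 80.0},
        )
        events = count_events(ft, self.SPECIES)
        assert len(events) == 1
        assert events[0].genes == {"a1", "a2", "a3"}

    def test_support_at_threshold_not_counted(self):
        ft = self._family_tree(
            "((a1:1,a2:1):1,(b1:1,c1:1):1,a3:1);",
            {frozenset({"a1", "a2"}): 50.0, frozenset({"b1", "c1"}): 49.0},
        )
        assert count_events(ft, self.SPECIES) == []

    def test_nested_clades_counted_once_maximal(self):
        ft = self._family_tree(
            "(((a1:1,a2:1):1,a3:1):1,b1:1,c1:1);",
            {frozenset({"a1", "a2"}): 95.0, frozenset({"a1", "a2", "a3"}): 90.0},
        )
        events = count_events(ft, self.SPECIES)
        assert len(events) == 1
        assert events[0].genes == {"a1", "a2", "a3"}
        total_genes = sum(len(e.genes) for e in events)
        assert total_genes == 3  # each gene once

    def test_event_genes_bounded_by_family_members(self):
        ft = self._family_tree(
            "((a1:1,a2:1):1,(b1:1,c1:1):1,a3:1);",
            {frozenset({"a1", "a2"}): 80.0},
        )
        for e in count_events(ft, self.SPECIES):
            assert e.genes <= {g for g, s in self.SPECIES.items() if s == e.species}
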