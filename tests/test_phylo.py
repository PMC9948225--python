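"""Alignment distance, neighbor joining, and clade assignment, each against
an independent oracle (recursive tuple-DP, exhaustive enumeration,
least-squares topology fitting, skbio's own NJ)."""

from functools import lru_cache
from itertools import combinations

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from terpscreen.phylo import (
    NOT_ASSIGNED,
    AlignmentScoring,
    assign_clades,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_align(a: str, b: str, match=1, mismatch=0, gap=-1):
    """Recursive DP maximizing (score, identities, aligned pairs) lexicographically."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        options = []
        if i < len(a) and j < len(b):
            s, d, p = best(i + 1, j + 1)
            eq = a[i] == b[j]
            options.append((s + (match if eq else mismatch), d + int(eq), p + 1))
        if i < len(a):
            s, d, p = best(i + 1, j)
            options.append((s + gap, d, p))
        if j < len(b):
            s, d, p = best(i, j + 1)
            options.append((s + gap, d, p))
        return max(options)

    return best(0, 0)


def oracle_distance(a, b):
    _, identities, pairs = oracle_align(a, b)
    return 1.0 - identities / (len(a) + len(b) - pairs)


def enumerate_alignments(a, b, match=1, mismatch=0, gap=-1):
    """Exhaustive alignment enumeration (tiny strings only)."""
    if not a and not b:
        yield (0, 0, 0)
        return
    if a and b:
        for s, d, p in enumerate_alignments(a[1:], b[1:], match, mismatch, gap):
            eq = a[0] == b[0]
            yield (s + (match if eq else mismatch), d + int(eq), p + 1)
    if a:
        for s, d, p in enumerate_alignments(a[1:], b, match, mismatch, gap):
            yield (s + gap, d, p)
    if b:
        for s, d, p in enumerate_alignments(a, b[1:], match, mismatch, gap):
            yield (s + gap, d, p)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with U(0.1, 2) edge lengths; returns (TreeNode, DistanceMatrix)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (i, j):
            nodes[k].length = float(rng.uniform(0.1, 2.0))
            parent.append(nodes[k])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = nodes[0]
    ids = [f"t{i}" for i in range(n_leaves)]
    return tree, DistanceMatrix(tree.tip_tip_distances(ids).data, ids)


def bipartitions(tree):
    """Non-trivial unrooted bipartitions as frozensets of the smaller-keyed side."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            bips.add(side if anchor in side else leaves - side)
    return bips


# ---------------------------------------------------------------------------
# pairwise distance
# ---------------------------------------------------------------------------

class TestPairwiseDistance:
    def test_identical_sequences(self):
        assert pairwise_distance("MSTLQA", "MSTLQA") == 0.0

    def test_disjoint_alphabets_equal_length(self):
        assert pairwise_distance("AAAAAA", "CCCCCC") == 1.0

    def test_single_mismatch_sixth(self):
        expected = max(enumerate_alignments("ACDEFG", "ACDEYG"))
        d = pairwise_distance("ACDEFG", "ACDEYG")
        assert d == pytest.approx(1 / 6)
        assert d == pytest.approx(1.0 - expected[1] / (12 - expected[2]))

    def test_matches_recursive_oracle_on_random_30mers(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aas, size=30)) for _ in range(8)]
        for a, b in combinations(seqs, 2):
            assert pairwise_distance(a, b) == pytest.approx(oracle_distance(a, b), abs=1e-12)

    def test_symmetry_under_varied_lengths(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(aas, size=int(rng.integers(5, 40))))
            assert pairwise_distance(a, b) == pairwise_distance(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "ACD")

    def test_non_integer_scoring_rejected(self):
        with pytest.raises(TypeError):
            AlignmentScoring(match=1.5)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float), list("abc"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 4.0}
        assert len(tree.children) == 3

    def test_four_taxon_topology_vs_least_squares(self, rng):
        # edges (1,2,3,4,5): pendants a=1 b=2 c=3 d=4, internal 5, true split ab|cd
        d = np.array(
            [[0, 8, 9, 10], [8, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
        )
        dm = DistanceMatrix(d, list("abcd"))
        # least-squares fit of all three unrooted 4-taxon topologies
        splits = {("a", "b"): None, ("a", "c"): None, ("a", "d"): None}
        pair_rows = list(combinations(range(4), 2))
        best_split, best_resid = None, np.inf
        for split in splits:
            i, j = [list("abcd").index(x) for x in split]
            others = [k for k in range(4) if k not in (i, j)]
            # columns: 4 pendant edges + internal edge
            A = np.zeros((6, 5))
            y = []
            for r, (p, q) in enumerate(pair_rows):
                A[r, p] += 1
                A[r, q] += 1
                same = {p, q} in ({i, j}, set(others))
                if not same:
                    A[r, 4] = 1
                y.append(d[p, q])
            resid = np.linalg.lstsq(A, np.array(y), rcond=None)[1]
            resid = float(resid[0]) if len(resid) else float(
                np.sum((A @ np.linalg.lstsq(A, np.array(y), rcond=None)[0] - y) ** 2)
            )
            if resid < best_resid:
                best_split, best_resid = split, resid
        assert best_split == ("a", "b")
        tree = neighbor_joining(dm)
        split_sides = bipartitions(tree)
        assert frozenset({"a", "b"}) in split_sides
        assert np.allclose(tree.tip_tip_distances(list("abcd")).data, d, atol=1e-9)

    def test_additive_recovery_random_trees(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 13))
            true_tree, dm = random_additive_tree(rng, n)
            nj = neighbor_joining(dm)
            assert bipartitions(nj) == bipartitions(true_tree)  # RF distance 0
            assert np.allclose(nj.tip_tip_distances(list(dm.ids)).data, dm.data, atol=1e-9)

    def test_matches_skbio_nj_on_additive_input(self, rng):
        from skbio.tree import nj as skbio_nj

        _, dm = random_additive_tree(rng, 8)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(theirs)

    def test_label_permutation_invariance(self, rng):
        _, dm = random_additive_tree(rng, 7)
        perm = rng.permutation(len(dm.ids))
        ids = [dm.ids[i] for i in perm]
        dm_perm = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids)
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm_perm)
        assert bipartitions(t1) == bipartitions(t2)
        assert np.allclose(
            t1.tip_tip_distances(list(dm.ids)).data,
            t2.tip_tip_distances(list(dm.ids)).data,
            atol=1e-9,
        )

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))
        with pytest.raises(Exception):  # asymmetric rejected by the container itself
            DistanceMatrix(np.array([[0, 1], [2, 0]], float), ["a", "b"])


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------

def _tree_from_newick(nwk):
    return TreeNode.read([nwk])


class TestAssignClades:
    REFS = {"r1": "III", "r2": "III", "r3": "IV", "r4": "IV", "r5": "V", "r6": "V"}

    def test_query_inside_pure_subtree(self):
        tree = _tree_from_newick(
            "(((r1:1,(q:0.2,r2:1):0.5):2,(r3:1,r4:1):2):1,(r5:1,r6:1):2);"
        )
        (a,) = assign_clades(tree, self.REFS, ["q"])
        assert a.clade == "III" and a.support == 1.0

    def test_central_orphan_not_assigned(self):
        # q hangs off the central edge with two clades on each side, so every
        # bipartition side containing q mixes clades (the orphan case)
        refs = dict(self.REFS, r7="VI", r8="VI")
        tree = _tree_from_newick(
            "(((r1:1,r2:1):2,(r3:1,r4:1):2):1,q:0.1,((r5:1,r6:1):2,(r7:1,r8:1):2):1);"
        )
        (a,) = assign_clades(tree, refs, ["q"])
        assert a.clade == NOT_ASSIGNED and a.support == 0.0

    def test_partial_subtree_gives_fractional_support(self):
        # q nests with only one of III's two references
        tree = _tree_from_newick(
            "(((q:0.2,r1:1):1,(r2:1,(r3:1,r4:1):1):1):1,(r5:1,r6:1):2);"
        )
        (a,) = assign_clades(tree, self.REFS, ["q"])
        assert a.clade == "III" and a.support == 0.5

    def test_no_queries_yields_empty_list(self):
        tree = _tree_from_newick("((r1:1,r2:1):1,(r3:1,r4:1):1,(r5:1,r6:1):1);")
        assert assign_clades(tree, self.REFS, []) == []

    def test_missing_query_rejected(self):
        tree = _tree_from_newick("((r1:1,r2:1):1,(r3:1,r4:1):1,(r5:1,r6:1):1);")
        with pytest.raises(ValueError, match="ghost"):
            assign_clades(tree, self.REFS, ["ghost"])

    def test_never_assigns_contaminated_bipartition(self, rng):
        """On a fixture tree, the assigned clade's defining side never contains
        another clade's reference."""
        from terpscreen.synth import make_clade_references

        fx = make_clade_references(4, 3, n_queries=4, seed=77)
        dm = distance_matrix(fx.all_records())
        tree = neighbor_joining(dm)
        labels = fx.reference_labels
        leaves = frozenset(t.name for t in tree.tips())
        for a in assign_clades(tree, labels, [q for q, _, _ in fx.queries]):
            assert a.clade != NOT_ASSIGNED
            # reconstruct the defining side and check purity independently
            sides = []
            for node in tree.postorder(include_self=False):
                side = frozenset(t.name for t in node.tips())
                side = side if a.query_id in side else leaves - side
                refs = {labels[r] for r in side & set(labels)}
                if refs == {a.clade}:
                    sides.append(side)
            assert sides, "assigned clade must come from at least one pure bipartition"
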