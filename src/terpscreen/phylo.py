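"""Distance-based phylogeny and clade assignment for synthase candidates.

Basidiomycete sesquiterpene synthases fall into a small number of discrete
clades (I-V in the reference classification), and clade membership loosely
predicts catalytic behaviour — clade III members, for instance, tend to be
single-product enzymes.  This module places candidate proteins on a
neighbor-joining tree together with clade-labelled references and assigns
each candidate the clade whose references it nests within, abstaining for
orphans that sit between clades.

Distances are global-alignment identity distances: d = 1 - identities /
aligned columns from a Needleman-Wunsch alignment with configurable integer
scoring (default match 1, mismatch 0, linear gap -1).  Among co-optimal
alignments the one maximizing identities and then the number of aligned
residue pairs is used, which makes the distance a well-defined function of
the sequence pair (and symmetric).

Trees are :class:`skbio.TreeNode` objects; neighbor joining is the classical
Saitou-Nei agglomeration with the Q criterion, implemented here so that
tie-breaking (lowest index pair) and negative-branch handling (clamp to zero,
deficit transferred to the sibling edge so the joined pair's path length is
preserved) are explicit and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentScoring",
    "CladeAssignment",
    "NOT_ASSIGNED",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "assign_clades",
    "clade_report_frame",
]

NOT_ASSIGNED = "not_assigned"


@dataclass(frozen=True)
class AlignmentScoring:
    """Integer Needleman-Wunsch scoring; integers keep the packed DP exact."""

    match: int = 1
    mismatch: int = 0
    gap: int = -1

    def __post_init__(self) -> None:
        for name in ("match", "mismatch", "gap"):
            if not isinstance(getattr(self, name), (int, np.integer)):
                raise TypeError(f"alignment {name} score must be an integer")


DEFAULT_SCORING = AlignmentScoring()


def _align_stats(a: str, b: str, scoring: AlignmentScoring) -> tuple[int, int, int]:
    """(score, identities, aligned_pairs) of the canonical optimal global alignment.

    Maximizes (score, identities, aligned residue pairs) lexicographically.
    The three quantities are packed into one int64 per DP cell
    (value = score*K^2 + identities*K + pairs with K > max length), so a
    single max-plus recurrence optimizes the full tuple.  The within-row
    dependency of the linear-gap recurrence is resolved with a running
    maximum: H[i,j] = G*j + cummax_j(A[j] - G*j) where A holds the
    diagonal/up candidates and G is the packed gap increment.
    """
    la, lb = len(a), len(b)
    K = max(la, lb) + 1
    K2 = K * K
    G = scoring.gap * K2
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    j_idx = np.arange(1, lb + 1, dtype=np.int64)
    prev = G * np.arange(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        eq = b_arr == a_arr[i - 1]
        diag_add = np.where(eq, scoring.match, scoring.mismatch).astype(np.int64) * K2 + eq * K + 1
        cand = np.maximum(prev[:-1] + diag_add, prev[1:] + G)
        shifted = np.empty(lb + 1, dtype=np.int64)
        shifted[0] = i * G
        shifted[1:] = cand - G * j_idx
        cur = np.maximum.accumulate(shifted)
        cur[1:] += G * j_idx
        prev = cur
    packed = int(prev[lb])
    pairs = packed % K
    rest = packed // K
    identities = rest % K
    score = rest // K
    return score, identities, pairs


def pairwise_distance(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Global-alignment identity distance in [0, 1].

    d = 1 - identities / aligned columns, where columns = len(a) + len(b) -
    aligned residue pairs.  Symmetric; zero iff the sequences are identical.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    score, identities, pairs = _align_stats(a.upper(), b.upper(), scoring)
    columns = len(a) + len(b) - pairs
    return 1.0 - identities / columns


def distance_matrix(
    records: Sequence[tuple[str, str]], scoring: AlignmentScoring = DEFAULT_SCORING
) -> DistanceMatrix:
    """All-pairs identity distances as an skbio DistanceMatrix."""
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(records[i][1], records[j][1], scoring)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamped_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative NJ branch estimate to zero, moving the deficit to the
    sibling edge so li + lj (the joined pair's path length) is preserved."""
    if li < 0:
        logger.debug("clamping negative NJ branch %.3g to 0", li)
        lj, li = max(lj + li, 0.0), 0.0
    elif lj < 0:
        logger.debug("clamping negative NJ branch %.3g to 0", lj)
        li, lj = max(li + lj, 0.0), 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    On an additive distance matrix the tip-to-tip path lengths of the result
    reproduce the input distances exactly (up to float round-off).  Ties in
    the Q criterion are broken by the lowest (row, column) index pair, so the
    topology is deterministic for a fixed input.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm[0], dtype=float), dm[1])
    if np.any(dm.data < 0):
        raise ValueError("distance matrix entries must be non-negative")
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major argmin = lowest-index tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamped_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        dnew = np.maximum(0.5 * (d[i, :] + d[j, :] - d[i, j]), 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dnew[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point formulas for the final star resolution
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        if length < 0:
            logger.debug("clamping negative terminal NJ branch %.3g to 0", length)
            length = 0.0
        node.length = length
        root.append(node)
    return root


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    clade: str  # a reference clade label or "not_assigned"
    support: float  # fraction of the assigned clade's references in the bipartition


def _leaf_sets(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf set under every non-root node — one per tree edge."""
    sets = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._leafset = frozenset([node.name])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.children))
        sets.append(node._leafset)
    return sets


def assign_clades(
    tree: TreeNode,
    reference_labels: Mapping[str, str],
    query_ids: Iterable[str],
) -> list[CladeAssignment]:
    """Assign each query leaf the clade whose references it nests within.

    A query is assigned clade C when the smallest bipartition of the tree that
    separates it from every other clade's references contains only clade-C
    references on the query's side — smallest separating side, i.e. the
    maximal pure clade-C context around the query; support is the fraction of
    C's references inside that side (so a query grafted inside a pure clade
    subtree scores 1.0, while one that splits a clade scores fractionally).
    If no pure bipartition exists at all — the orphan case, a query attached
    between clades — the result is ``not_assigned`` with support 0.
    """
    leaves = {tip.name for tip in tree.tips()}
    missing_refs = set(reference_labels) - leaves
    if missing_refs:
        raise ValueError(f"reference leaves missing from tree: {sorted(missing_refs)}")
    ref_ids = set(reference_labels)
    clade_sizes: dict[str, int] = {}
    for clade in reference_labels.values():
        clade_sizes[clade] = clade_sizes.get(clade, 0) + 1

    sides = _leaf_sets(tree)
    assignments = []
    for q in query_ids:
        if q not in leaves:
            raise ValueError(f"query {q!r} is not a leaf of the tree")
        best: tuple[int, str, float] | None = None
        for side in sides:
            q_side = side if q in side else leaves - side
            refs_in = q_side & ref_ids
            if not refs_in:
                continue
            clades_in = {reference_labels[r] for r in refs_in}
            if len(clades_in) != 1:
                continue
            clade = next(iter(clades_in))
            # minimize the separating side = maximize the query's pure side
            cand = (len(leaves) - len(q_side), clade, len(refs_in) / clade_sizes[clade])
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        if best is None:
            assignments.append(CladeAssignment(q, NOT_ASSIGNED, 0.0))
        else:
            assignments.append(CladeAssignment(q, best[1], best[2]))
    return assignments


def clade_report_frame(assignments: Sequence[CladeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [a.query_id for a in assignments],
            "clade": [a.clade for a in assignments],
            "support": [round(a.support, 4) for a in assignments],
        }
    )
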