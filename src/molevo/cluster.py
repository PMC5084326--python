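"""Dataset decomposition for phylogenetic workflows.

Three strategies plus a counting utility:

* ``naive_rows`` — balanced disjoint blocks of whole sequences;
* ``naive_cols`` — column ranges sized from the longest sequence;
* ``prd_decompose`` — phylogeny-guided overlapping decomposition: a
  worklist repeatedly splits any over-size leaf set at the centroid edge
  of its (induced) tree and pads each side with the topologically nearest
  leaves of the other side, giving bounded-size, overlapping subsets;
* ``count_unrooted_topologies`` — the number of binary unrooted
  topologies on k leaves, (2k−5)!! = (2k−5)!/[2^(k−3) (k−3)!].

Everything is deterministic; all ties are broken lexicographically.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import dendropy

from .errors import ValidationError
from .genes import Fragment
from .records import AnnotatedRecord, Locus

__all__ = [
    "Decomposition",
    "naive_rows",
    "naive_cols",
    "prd_decompose",
    "count_unrooted_topologies",
]


def naive_rows(
    records: Sequence[AnnotatedRecord], k: int
) -> dict[str, list[AnnotatedRecord]]:
    """Split into ``k`` contiguous, order-preserving blocks whose sizes
    differ by at most one (the first ``n mod k`` blocks take the extra)."""
    n = len(records)
    if k < 1:
        raise ValidationError(f"number of sets must be >= 1, got {k}")
    if k > n:
        raise ValidationError(f"cannot split {n} records into {k} sets")
    base, extra = divmod(n, k)
    out: dict[str, list[AnnotatedRecord]] = {}
    pos = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        out[f"set{i:03d}"] = list(records[pos : pos + size])
        pos += size
    return out


def naive_cols(
    records: Sequence[AnnotatedRecord], k: int
) -> dict[str, list[Fragment]]:
    """Split by column ranges of length ``ceil(L/k)`` where ``L`` is the
    longest sequence; every set holds one (possibly empty) fragment per
    record, clipped to that record's own length."""
    if not records:
        raise ValidationError("naive_cols requires at least one record")
    if k < 1:
        raise ValidationError(f"number of sets must be >= 1, got {k}")
    longest = max(len(r.sequence) for r in records)
    if k > longest:
        raise ValidationError(
            f"cannot split length-{longest} sequences into {k} column ranges"
        )
    width = -(-longest // k)
    out: dict[str, list[Fragment]] = {}
    for i in range(k):
        start, end = i * width, min((i + 1) * width, longest)
        fragments = []
        for record in records:
            lo, hi = min(start, len(record.sequence)), min(end, len(record.sequence))
            loci = (Locus(lo, hi),) if hi > lo else ()
            fragments.append(Fragment(record.id, record.sequence[lo:hi], loci))
        out[f"set{i:03d}"] = fragments
    return out


@dataclass(frozen=True)
class Decomposition:
    """Overlapping leaf-label subsets plus the parameters that shaped them."""

    sets: tuple[frozenset[str], ...]
    max_size: int
    overlap: int

    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s
        return frozenset(out)


def _adjacency(tree: dendropy.Tree):
    adj: dict[int, list[int]] = {}
    leaf_of: dict[int, str] = {}
    nodes = {}
    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.is_leaf():
            leaf_of[id(node)] = node.taxon.label
        for child in node.child_nodes():
            adj.setdefault(id(child), [])
            adj[id(node)].append(id(child))
            adj[id(child)].append(id(node))
    return adj, leaf_of, nodes


def _leafsets_below(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= below[id(child)]
            below[id(node)] = frozenset(acc)
    return below


def _centroid_split(tree: dendropy.Tree):
    """Edge minimizing the larger side's leaf count; ties by the
    lexicographically smallest label on the smaller side.  Returns
    (small side, large side, child node id of the cut edge)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    below = _leafsets_below(tree)
    best = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side_a = below[id(node)]
        side_b = all_leaves - side_a
        if not side_a or not side_b:
            continue
        small, large = sorted((side_a, side_b), key=lambda s: (len(s), min(s)))
        key = (len(large), min(small))
        if best is None or key < best[0]:
            best = (key, small, large, id(node))
    if best is None:
        raise ValidationError("tree has no splittable edge")
    return best[1], best[2], best[3]


def _pad_distances(tree: dendropy.Tree, cut_child_id: int):
    """Topological distance (edge count) of every leaf to the cut edge,
    measured to the cut endpoint on the leaf's own side."""
    adj, leaf_of, _ = _adjacency(tree)
    parent_id = None
    # locate the parent endpoint of the cut edge
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if id(child) == cut_child_id:
                parent_id = id(node)
    dist: dict[str, int] = {}
    for start, blocked in ((cut_child_id, parent_id), (parent_id, cut_child_id)):
        seen = {start, blocked}
        queue = deque([(start, 0)])
        while queue:
            nid, d = queue.popleft()
            if nid in leaf_of:
                dist[leaf_of[nid]] = d
            for nxt in adj[nid]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append((nxt, d + 1))
    return dist


def _induced(tree: dendropy.Tree, labels: frozenset[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(labels=labels)
    sub.purge_taxon_namespace()
    return sub


def prd_decompose(
    tree: dendropy.Tree, max_size: int, overlap: int
) -> Decomposition:
    """Phylogeny-guided overlapping decomposition (worklist algorithm).

    A queue starts with the full leaf set; any popped set within
    ``max_size`` is emitted, otherwise its induced tree is split at the
    centroid edge and each side is padded with up to ``overlap``
    topologically nearest leaves from the other side (padding is trimmed
    when needed so each queued subproblem is strictly smaller than its
    parent, which guarantees termination).  Polytomies are resolved with
    zero-length edges for the centroid search.
    """
    if overlap < 0:
        raise ValidationError(f"overlap must be >= 0, got {overlap}")
    if overlap >= max_size - 1:
        raise ValidationError(
            f"overlap ({overlap}) must be <= max_size - 2 ({max_size - 2})"
        )
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    all_leaves = frozenset(l.taxon.label for l in work.leaf_node_iter())
    if len(all_leaves) < 3:
        raise ValidationError("decomposition requires at least 3 leaves")

    emitted: list[frozenset[str]] = []
    queue: deque[tuple[frozenset[str], dendropy.Tree]] = deque(
        [(all_leaves, work)]
    )
    while queue:
        leaves, subtree = queue.popleft()
        if len(leaves) <= max_size:
            emitted.append(leaves)
            continue
        small, large, cut_child = _centroid_split(subtree)
        dist = _pad_distances(subtree, cut_child)
        for side, other in ((small, large), (large, small)):
            pad_n = min(overlap, len(leaves) - len(side) - 1)
            padding = sorted(other, key=lambda l: (dist[l], l))[:pad_n]
            padded = side | frozenset(padding)
            sub = _induced(subtree, padded)
            sub.resolve_polytomies()
            queue.append((padded, sub))
    emitted.sort(key=lambda s: sorted(s))
    return Decomposition(tuple(emitted), max_size, overlap)


def count_unrooted_topologies(k: int) -> int:
    """Exact number of binary unrooted topologies on ``k`` labeled leaves,
    the double factorial (2k−5)!!."""
    if k < 3:
        raise ValidationError(f"topology count requires k >= 3, got {k}")
    out = 1
    for odd in range(1, 2 * k - 4, 2):
        out *= odd
    return out
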