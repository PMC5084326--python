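"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
plain recursion over all global alignments, a tiny hand-rolled newick
clade extractor for bipartition counting, and exhaustive stepwise-addition
enumeration of unrooted topologies.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable


def best_alignment_score_by_enumeration(
    ref: str, query: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Maximum global alignment score by enumerating every alignment path
    (no memoization — this really walks all of them)."""

    def rec(i: int, j: int) -> int:
        if i == len(ref) and j == len(query):
            return 0
        scores = []
        if i < len(ref) and j < len(query):
            scores.append(
                (match if ref[i] == query[j] else mismatch) + rec(i + 1, j + 1)
            )
        if j < len(query):
            scores.append(gap + rec(i, j + 1))
        if i < len(ref):
            scores.append(gap + rec(i + 1, j))
        return max(scores)

    return rec(0, 0)


def newick_clades(newick: str) -> tuple[frozenset[str], list[frozenset[str]]]:
    """(all leaves, one leaf-set per internal node below the root) from a
    newick string, via a minimal recursive parser."""
    text = newick.strip().rstrip(";")
    pos = 0
    clades: list[frozenset[str]] = []

    def parse() -> frozenset[str]:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            leaves: set[str] = set()
            while True:
                leaves |= parse()
                if text[pos] == ",":
                    pos += 1
                    continue
                assert text[pos] == ")"
                pos += 1
                break
            # skip any label / branch length after the group
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            clades.append(frozenset(leaves))
            return frozenset(leaves)
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        label = text[start:pos]
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        return frozenset([label])

    root = parse()
    # the root clade is the full leaf set, not an internal edge
    return root, [c for c in clades if c != root]


def bipartition_frequencies_from_newick(
    newicks: Iterable[str],
) -> dict[frozenset[str], float]:
    """Non-trivial bipartition frequencies over newick strings, with the
    canonical side excluding the smallest leaf label."""
    newicks = list(newicks)
    counts: Counter[frozenset[str]] = Counter()
    leaves = None
    for nwk in newicks:
        all_leaves, clades = newick_clades(nwk)
        leaves = all_leaves if leaves is None else leaves
        assert all_leaves == leaves
        anchor = min(leaves)
        per_tree = set()
        for clade in clades:
            side = leaves - clade if anchor in clade else clade
            if 2 <= len(side) <= len(leaves) - 2:
                per_tree.add(side)
        counts.update(per_tree)
    return {b: c / len(newicks) for b, c in counts.items()}


def count_topologies_by_enumeration(k: int) -> int:
    """Number of distinct binary unrooted topologies on k labeled leaves,
    by generating every stepwise-addition outcome and deduplicating on
    the canonical bipartition set."""
    assert k >= 3

    def rec(edges, next_leaf, next_internal):
        if next_leaf == k:
            yield edges
            return
        for idx in range(len(edges)):
            u, v = edges[idx]
            w = next_internal
            new = (
                edges[:idx]
                + [(u, w), (w, v), (w, next_leaf)]
                + edges[idx + 1 :]
            )
            yield from rec(new, next_leaf + 1, next_internal + 1)

    def canonical(edges) -> frozenset[frozenset[int]]:
        adj: dict[int, list[int]] = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        splits = set()
        for u, v in edges:
            # leaves reachable from v without crossing (u, v)
            stack, seen = [v], {u, v}
            side = set()
            while stack:
                node = stack.pop()
                if node < k:
                    side.add(node)
                for nxt in adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if 0 in side:
                side = set(range(k)) - side
            if 2 <= len(side) <= k - 2:
                splits.add(frozenset(side))
        return frozenset(splits)

    start = [(0, k), (1, k), (2, k)]
    return len({canonical(e) for e in rec(start, 3, k + 1)})
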