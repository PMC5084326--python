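"""Majority-rule consensus trees, implemented natively.

A bipartition is the two-way split of the leaf set induced by removing
one edge; its canonical form here is the side that excludes the globally
smallest leaf label.  The strict majority-rule consensus contains exactly
the non-trivial bipartitions occurring in more than a threshold fraction
(default 1/2) of the input trees — for thresholds >= 1/2 those are
pairwise compatible, so their canonical sides form a laminar family and
assemble directly into a tree.  The *extended* variant greedily adds the
remaining bipartitions, in descending frequency (ties lexicographic),
whenever compatible.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import dendropy

from .errors import ValidationError
from .treeio import leaf_labels

__all__ = [
    "bipartition_frequencies",
    "majority_rule_consensus",
]


def _tree_bipartitions(tree: dendropy.Tree, leaves: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial canonical bipartitions of one (unrooted) tree."""
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= below[id(child)]
            below[id(node)] = frozenset(acc)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = below[id(node)]
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bipartition_frequencies(
    trees: Sequence[dendropy.Tree],
) -> dict[frozenset[str], float]:
    """Fraction of input trees containing each non-trivial bipartition."""
    trees = list(trees)
    if not trees:
        raise ValidationError("need at least one input tree")
    leaf_sets = [leaf_labels(t) for t in trees]
    reference = leaf_sets[0]
    for labels in leaf_sets[1:]:
        if labels != reference:
            diff = sorted(labels ^ reference)
            raise ValidationError(
                f"input trees differ in leaf sets; symmetric difference: {diff}"
            )
    counts: Counter[frozenset[str]] = Counter()
    for tree in trees:
        counts.update(_tree_bipartitions(tree, reference))
    return {b: c / len(trees) for b, c in counts.items()}


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    # canonical sides exclude the anchor label, so compatibility reduces
    # to nested-or-disjoint
    return a <= b or b <= a or not (a & b)


def majority_rule_consensus(
    trees: Sequence[dendropy.Tree],
    threshold: float = 0.5,
    extended: bool = False,
) -> dendropy.Tree:
    """Consensus tree over trees sharing one leaf set.

    Contains exactly the bipartitions with frequency strictly above
    ``threshold`` (plus, with ``extended``, greedily compatible minority
    bipartitions).  Edge support is stored as internal-node labels,
    percentages with one decimal place.
    """
    if not (0.5 <= threshold < 1.0):
        raise ValidationError(
            f"threshold must lie in [0.5, 1) so majority bipartitions are "
            f"pairwise compatible; got {threshold}"
        )
    trees = list(trees)
    freqs = bipartition_frequencies(trees)
    leaves = leaf_labels(trees[0])

    selected = {b: f for b, f in freqs.items() if f > threshold}
    if extended:
        remaining = sorted(
            (b for b in freqs if b not in selected),
            key=lambda b: (-freqs[b], sorted(b)),
        )
        for cand in remaining:
            if all(_compatible(cand, kept) for kept in selected):
                selected[cand] = freqs[cand]

    # laminar assembly: larger clades first, each nested under the
    # smallest already-placed clade containing it
    taxa = dendropy.TaxonNamespace(sorted(leaves))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False
    root = tree.seed_node
    root_set = frozenset(leaves)
    nodes: dict[frozenset[str], dendropy.Node] = {root_set: root}
    for clade in sorted(selected, key=lambda b: (-len(b), sorted(b))):
        parent_set = min(
            (s for s in nodes if clade < s or s == root_set),
            key=len,
        )
        node = dendropy.Node()
        node.label = f"{selected[clade] * 100:.1f}"
        nodes[parent_set].add_child(node)
        nodes[clade] = node
    for label in sorted(leaves):
        parent_set = min((s for s in nodes if label in s), key=len)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[parent_set].add_child(leaf)
    return tree
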