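"""Thin newick I/O helpers on top of DendroPy.

Trees are plain :class:`dendropy.Tree` objects throughout the toolkit;
these helpers only pin down schema details (newick, preserved underscores)
so every module reads and writes trees the same way.
"""

from __future__ import annotations

from typing import IO, Iterable

import dendropy

from .errors import ParseError

__all__ = ["read_trees", "write_trees", "leaf_labels"]


def read_trees(source: str | IO[str]) -> dendropy.TreeList:
    """Read one or more newick trees from a path, handle or newick text."""
    if not isinstance(source, str):
        source = source.read()
    try:
        if "(" in source and ";" in source:
            return dendropy.TreeList.get(
                data=source, schema="newick", preserve_underscores=True
            )
        return dendropy.TreeList.get(
            path=source, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"could not parse newick input: {exc}") from exc


def write_trees(trees: Iterable[dendropy.Tree], dest: str | IO[str]) -> None:
    text = "".join(
        t.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        for t in trees
    )
    if isinstance(dest, str):
        with open(dest, "w") as handle:
            handle.write(text)
    else:
        dest.write(text)


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
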