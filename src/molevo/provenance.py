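"""Data collections with a provenance ledger (report files).

A :class:`DataCollection` holds sequence records or trees together with
an ordered source history and an override ledger: whenever a merged
source re-uses an existing identifier, the incoming item replaces the
stored one and the collision is recorded.  The report file (``.rep``
sidecar, same basename as the data file) serializes the item count, the
sources and the overrides, and can stand in for a large data file when
sharing an analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Callable, Iterable, Mapping, Sequence

import dendropy

from .errors import ParseError, ValidationError
from .records import AnnotatedRecord, write_genbank
from .treeio import write_trees

__all__ = [
    "SourceEntry",
    "Override",
    "DataCollection",
    "merge_source",
    "write_report",
    "parse_report",
    "save_collection",
    "compute_batch_size",
    "update_diff",
    "apply_remote_update",
]


@dataclass(frozen=True)
class SourceEntry:
    """One data source: when it was accessed, where it came from and how
    many items it contributed."""

    timestamp: str
    origin: str
    count: int

    def __post_init__(self) -> None:
        try:
            datetime.fromisoformat(self.timestamp)
        except ValueError as exc:
            raise ValidationError(
                f"timestamp {self.timestamp!r} is not ISO-8601"
            ) from exc
        if self.count < 0:
            raise ValidationError("source count must be >= 0")


@dataclass(frozen=True)
class Override:
    """An identifier collision: the incoming item replaced the stored one."""

    item_id: str
    old_version: int
    new_version: int
    source_index: int


@dataclass
class DataCollection:
    """Records or trees plus their source-history ledger."""

    items: dict[str, object] = field(default_factory=dict)
    history: list[SourceEntry] = field(default_factory=list)
    overrides: list[Override] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)


def _item_version(item: object) -> int:
    return int(getattr(item, "version", 1))


def merge_source(
    coll: DataCollection,
    items: Iterable[tuple[str, object]] | Mapping[str, object] | Sequence,
    origin: str,
    timestamp: str,
) -> DataCollection:
    """Merge one source into the collection (non-destructively).

    ``items`` may be a mapping id→item, (id, item) pairs, or objects with
    an ``id`` attribute.  On id collision the incoming item wins and an
    override entry referencing this source is appended.  The history
    gains exactly one entry.
    """
    if isinstance(items, Mapping):
        pairs = list(items.items())
    else:
        pairs = [
            it if isinstance(it, tuple) else (it.id, it) for it in items
        ]
    new_items = dict(coll.items)
    new_overrides = list(coll.overrides)
    source_index = len(coll.history)
    for item_id, item in pairs:
        if item_id in new_items:
            new_overrides.append(
                Override(
                    item_id,
                    _item_version(new_items[item_id]),
                    _item_version(item),
                    source_index,
                )
            )
        new_items[item_id] = item
    entry = SourceEntry(timestamp=timestamp, origin=origin, count=len(pairs))
    return DataCollection(new_items, coll.history + [entry], new_overrides)


def write_report(coll: DataCollection, path: str) -> None:
    """Serialize count, sources and overrides (tab-separated, UTF-8)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"count: {len(coll)}\n")
        for entry in coll.history:
            handle.write(
                f"source:\t{entry.timestamp}\t{entry.origin}\t{entry.count}\n"
            )
        for ov in coll.overrides:
            handle.write(
                f"override:\t{ov.item_id}\t{ov.old_version}\t"
                f"{ov.new_version}\t{ov.source_index}\n"
            )


def parse_report(path: str) -> tuple[int, list[SourceEntry], list[Override]]:
    """Inverse of :func:`write_report`; malformed lines are reported with
    their line number."""
    history: list[SourceEntry] = []
    overrides: list[Override] = []
    count = None
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                if line.startswith("count:"):
                    count = int(line.split(":", 1)[1].strip())
                elif line.startswith("source:\t"):
                    _, timestamp, origin, n = line.split("\t")
                    history.append(SourceEntry(timestamp, origin, int(n)))
                elif line.startswith("override:\t"):
                    _, item_id, old, new, idx = line.split("\t")
                    overrides.append(Override(item_id, int(old), int(new), int(idx)))
                else:
                    raise ValueError(f"unrecognized line {line!r}")
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if count is None:
        raise ParseError(f"{path}: missing 'count:' header")
    for ov in overrides:
        if not (0 <= ov.source_index < len(history)):
            raise ParseError(
                f"{path}: override for {ov.item_id!r} references source "
                f"index {ov.source_index} outside the history"
            )
    return count, history, overrides


def save_collection(coll: DataCollection, path: str) -> str:
    """Write the data file (GenBank for sequence records, newick for
    trees) plus the ``.rep`` report beside it; returns the report path."""
    items = list(coll.items.values())
    if items and isinstance(items[0], dendropy.Tree):
        write_trees(items, path)
    else:
        write_genbank(items, path)
    report_path = os.path.splitext(path)[0] + ".rep"
    write_report(coll, report_path)
    return report_path


def compute_batch_size(
    avg_record_bytes: int, byte_budget: int = 16 * 1024 * 1024, cap: int = 500
) -> int:
    """Records per fetch batch so one batch stays within a byte budget
    (the offline stand-in for bandwidth × maximum download time), capped."""
    if avg_record_bytes <= 0 or byte_budget <= 0 or cap < 1:
        raise ValidationError("batch-size inputs must be positive")
    return min(cap, max(1, byte_budget // avg_record_bytes))


def update_diff(
    local: Mapping[str, int], remote: Mapping[str, int]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Version-based incremental update plan.

    Returns ``(fetch, delete, keep)``: fetch ids that are remote-only or
    remotely newer, delete local-only ids, keep ids whose versions match.
    The three sets partition ``local ∪ remote``.
    """
    for versions in (local, remote):
        for item_id, version in versions.items():
            if version < 1:
                raise ValidationError(f"version of {item_id!r} must be >= 1")
    fetch = {i for i in remote if i not in local or remote[i] > local[i]}
    delete = {i for i in local if i not in remote}
    keep = {i for i in local if i in remote and remote[i] <= local[i]}
    return frozenset(fetch), frozenset(delete), frozenset(keep)


def apply_remote_update(
    coll: DataCollection,
    remote_versions: Mapping[str, int],
    fetch: Callable[[Sequence[str]], Iterable[tuple[str, object]]],
    origin: str,
    timestamp: str,
    max_records: int | None = None,
) -> DataCollection:
    """Update the collection against an injected remote index.

    ``fetch`` is the transport (tests inject a recorded/mock one); the
    toolkit itself performs no network access.  ``max_records`` truncates
    the fetch list for representative-sample retrievals.
    """
    local_versions = {i: _item_version(v) for i, v in coll.items.items()}
    to_fetch, to_delete, _ = update_diff(local_versions, remote_versions)
    kept = {i: v for i, v in coll.items.items() if i not in to_delete}
    base = replace(coll, items=kept)
    wanted = sorted(to_fetch)
    if max_records is not None:
        wanted = wanted[:max_records]
    fetched = list(fetch(wanted)) if wanted else []
    return merge_source(base, fetched, origin, timestamp)
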