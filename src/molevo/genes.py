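"""Annotation-driven gene partitioning with low-support error detection.

The method treats every qualifier value of every (filtered) feature
instance as evidence of gene identity.  Normalized values become nodes of
a term graph; values co-occurring within one feature instance are linked,
each link remembering the records that support it.  Connected components
of the graph then define the gene sets — so a gene annotated under
several nomenclatures ("ATP6", "atpase 6", "ATP synthase F0 subunit 6")
still collapses to one set as long as at least one record bridges the
vocabularies.  Edges whose record support is anomalously low relative to
the sampling depth of their endpoints flag likely annotation errors
(e.g. a record carrying another gene's product name); they are reported,
and optionally removed, rather than silently trusted.

Records without usable annotation can be annotated first by projecting a
reference sequence's loci onto them (see :mod:`molevo.liftover`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple, Sequence

import networkx as nx

from .errors import ValidationError
from .liftover import transfer_loci
from .records import AnnotatedRecord, Feature, Locus

__all__ = [
    "Term",
    "TermGraph",
    "UncertainPair",
    "Fragment",
    "PartitionResult",
    "normalize_term",
    "build_term_graph",
    "detect_uncertain_pairs",
    "write_uncertain_log",
    "partition_genes",
]


class Term(NamedTuple):
    """A node of the term graph: a feature kind plus a normalized value."""

    kind: str
    text: str


def normalize_term(raw: str) -> str:
    """Normal form of a qualifier value: surrounding quotes stripped,
    case-folded, whitespace trimmed and collapsed to single spaces."""
    text = raw.strip()
    while len(text) >= 2 and text[0] == text[-1] and text[0] in "\"'":
        text = text[1:-1].strip()
    text = " ".join(text.casefold().split())
    if not text:
        raise ValidationError(f"qualifier value {raw!r} is empty after normalization")
    return text


class TermGraph:
    """Co-occurrence graph of annotation terms with per-record support.

    ``n(term)`` is the number of distinct records in which the term was
    observed; each edge stores the set of record ids whose single feature
    instance linked the two endpoint terms.
    """

    def __init__(self) -> None:
        self._term_records: dict[Term, set[str]] = {}
        self._edge_support: dict[tuple[Term, Term], set[str]] = {}

    @staticmethod
    def _key(a: Term, b: Term) -> tuple[Term, Term]:
        return (a, b) if a <= b else (b, a)

    def add_instance(self, record_id: str, terms: Iterable[Term]) -> None:
        """Register one feature instance of ``record_id`` bearing ``terms``."""
        terms = sorted(set(terms))
        for term in terms:
            self._term_records.setdefault(term, set()).add(record_id)
        for i, a in enumerate(terms):
            for b in terms[i + 1 :]:
                self._edge_support.setdefault((a, b), set()).add(record_id)

    @property
    def terms(self) -> list[Term]:
        return sorted(self._term_records)

    def n(self, term: Term) -> int:
        return len(self._term_records.get(term, ()))

    def records_of(self, term: Term) -> frozenset[str]:
        return frozenset(self._term_records.get(term, ()))

    def edges(self) -> list[tuple[Term, Term, frozenset[str]]]:
        return [
            (a, b, frozenset(sup))
            for (a, b), sup in sorted(self._edge_support.items())
        ]

    def support(self, a: Term, b: Term) -> frozenset[str]:
        return frozenset(self._edge_support.get(self._key(a, b), ()))

    def __len__(self) -> int:
        return len(self._term_records)

    def to_networkx(self, *, drop_edges: Iterable[tuple[Term, Term]] = ()) -> nx.Graph:
        dropped = {self._key(a, b) for a, b in drop_edges}
        graph = nx.Graph()
        graph.add_nodes_from(self._term_records)
        graph.add_edges_from(k for k in self._edge_support if k not in dropped)
        return graph

    def components(
        self, *, drop_edges: Iterable[tuple[Term, Term]] = ()
    ) -> list[frozenset[Term]]:
        comps = nx.connected_components(self.to_networkx(drop_edges=drop_edges))
        return sorted((frozenset(c) for c in comps), key=lambda c: sorted(c))


@dataclass(frozen=True)
class UncertainPair:
    """A term-graph edge whose record support fell below the sampling
    threshold — the signature of a likely annotation error."""

    term_a: Term
    term_b: Term
    supporting_record_ids: tuple[str, ...]
    support_count: int
    threshold_used: int


@dataclass(frozen=True)
class Fragment:
    """One extracted gene region: provenance plus residues."""

    record_id: str
    residues: str
    loci: tuple[Locus, ...]


@dataclass
class PartitionResult:
    """Gene sets plus the error log of the run."""

    sets: dict[str, list[Fragment]]
    uncertain: list[UncertainPair]
    unassignable: list[str]
    graph: TermGraph

    def __len__(self) -> int:
        return len(self.sets)


def _instance_terms(
    feature: Feature,
    colocated_gene_values: dict[tuple, list[str]],
    qualifier_mode: str,
) -> frozenset[Term]:
    if qualifier_mode == "all":
        values = feature.values()
    elif qualifier_mode in ("gene", "product"):
        values = feature.values([qualifier_mode])
    else:
        raise ValidationError(
            f"qualifier_mode must be 'gene', 'product' or 'all', got {qualifier_mode!r}"
        )
    signature = tuple((l.start, l.end, l.strand) for l in feature.loci)
    values = list(values) + colocated_gene_values.get(signature, [])
    return frozenset(Term(feature.kind, normalize_term(v)) for v in values)


def _iter_instances(
    record: AnnotatedRecord,
    feature_filter: set[str],
    qualifier_mode: str,
) -> list[tuple[Feature, frozenset[Term]]]:
    # "gene" features sharing the exact loci of a filtered feature lend it
    # their values (conservative co-location: identical intervals only),
    # under the same qualifier restriction as the instance itself.
    names = None if qualifier_mode == "all" else [qualifier_mode]
    colocated: dict[tuple, list[str]] = {}
    for feat in record.features:
        if feat.kind == "gene" and "gene" not in feature_filter:
            sig = tuple((l.start, l.end, l.strand) for l in feat.loci)
            colocated.setdefault(sig, []).extend(feat.values(names))
    out = []
    for feat in record.features:
        if feat.kind in feature_filter:
            out.append((feat, _instance_terms(feat, colocated, qualifier_mode)))
    return out


def build_term_graph(
    records: Sequence[AnnotatedRecord],
    feature_filter: Iterable[str],
    qualifier_mode: str = "all",
) -> TermGraph:
    """Build the term co-occurrence graph over the filtered features.

    ``qualifier_mode`` selects the evidence: the classical single-qualifier
    approaches (``gene`` or ``product``) or ``all`` qualifier values, which
    is what lets inconsistent nomenclatures merge.
    """
    feature_filter = set(feature_filter)
    if not feature_filter:
        raise ValidationError("feature_filter must be non-empty")
    graph = TermGraph()
    for record in records:
        for _feat, terms in _iter_instances(record, feature_filter, qualifier_mode):
            if terms:
                graph.add_instance(record.id, terms)
    return graph


def detect_uncertain_pairs(
    graph: TermGraph,
    rate: float = 0.05,
    floor: int = 2,
    log: str | IO[str] | None = None,
) -> list[UncertainPair]:
    """Flag edges with anomalously low record support.

    An edge (a, b) is uncertain iff
    ``|support(a, b)| < max(floor, ceil(rate * min(n_a, n_b)))`` — a link
    seen in almost no records although both of its terms are well sampled
    is far more likely an annotation error than a rare nomenclature.
    Returned sorted by ascending support; optionally serialized to ``log``.
    """
    if not (0.0 < rate < 1.0):
        raise ValidationError(f"rate must be in (0, 1), got {rate}")
    if floor < 1:
        raise ValidationError(f"floor must be >= 1, got {floor}")
    flagged = []
    for a, b, support in graph.edges():
        threshold = max(floor, math.ceil(rate * min(graph.n(a), graph.n(b))))
        if len(support) < threshold:
            flagged.append(
                UncertainPair(a, b, tuple(sorted(support)), len(support), threshold)
            )
    flagged.sort(key=lambda u: (u.support_count, u.term_a, u.term_b))
    if log is not None:
        write_uncertain_log(flagged, log)
    return flagged


def write_uncertain_log(pairs: Sequence[UncertainPair], dest: str | IO[str]) -> None:
    """One block per pair: ``term_a <TAB> term_b <TAB> count`` followed by
    one indented line per supporting record id."""
    lines = []
    for pair in pairs:
        lines.append(
            f"{pair.term_a.kind}:{pair.term_a.text}\t"
            f"{pair.term_b.kind}:{pair.term_b.text}\t{pair.support_count}\n"
        )
        lines.extend(f"\t{rid}\n" for rid in pair.supporting_record_ids)
    text = "".join(lines)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as handle:
            handle.write(text)
    else:
        dest.write(text)


def _set_identifier(component: frozenset[Term], graph: TermGraph) -> str:
    best = min(component, key=lambda t: (-graph.n(t), t.text))
    return f"{best.kind}_{best.text}"


def partition_genes(
    records: Sequence[AnnotatedRecord],
    feature_filter: Iterable[str],
    qualifier_mode: str = "all",
    *,
    drop_uncertain: bool = False,
    refseq: AnnotatedRecord | None = None,
    rate: float = 0.05,
    floor: int = 2,
    log: str | IO[str] | None = None,
) -> PartitionResult:
    """Partition records into per-gene fragment sets.

    Connected components of the term graph (optionally after removing
    uncertain edges) define gene identities; every feature instance that
    bears any of a component's terms contributes one extracted fragment to
    that component's set, so two loci annotated under one name land in the
    same set.  Records carrying no filtered feature are first annotated by
    reference projection when ``refseq`` is given, and reported as
    unassignable otherwise.  Set identifiers are ``kind_term`` with the
    component's most frequent term (ties broken lexicographically).
    """
    records = list(records)
    if not records:
        return PartitionResult({}, [], [], TermGraph())
    feature_filter = set(feature_filter)
    if refseq is not None and not refseq.features:
        raise ValidationError("reference record carries no features")

    unassignable: list[str] = []
    prepared: list[AnnotatedRecord] = []
    for record in records:
        if not record.features_of_kind(feature_filter):
            if refseq is not None:
                record = transfer_loci(refseq, record)
                if not record.features_of_kind(feature_filter):
                    unassignable.append(record.id)
                    continue
            else:
                unassignable.append(record.id)
                continue
        prepared.append(record)

    graph = build_term_graph(prepared, feature_filter, qualifier_mode)
    uncertain = detect_uncertain_pairs(graph, rate=rate, floor=floor, log=log)
    drop = [(u.term_a, u.term_b) for u in uncertain] if drop_uncertain else []
    components = graph.components(drop_edges=drop)

    term_to_sets: dict[Term, list[str]] = {}
    sets: dict[str, list[Fragment]] = {}
    for component in components:
        identifier = _set_identifier(component, graph)
        sets[identifier] = []
        for term in component:
            term_to_sets.setdefault(term, []).append(identifier)

    for record in prepared:
        for feat, terms in _iter_instances(record, feature_filter, qualifier_mode):
            if not terms:
                continue
            targets = sorted({s for t in terms for s in term_to_sets.get(t, ())})
            if not targets:
                continue
            fragment = Fragment(record.id, record.extract(feat.loci), feat.loci)
            for identifier in targets:
                sets[identifier].append(fragment)

    return PartitionResult(sets, uncertain, unassignable, graph)
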