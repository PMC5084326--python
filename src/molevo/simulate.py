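"""Seeded synthetic fixtures: annotated mtDNA-style panels and tree sets.

The panel generator emulates the *annotation structure* of a human
mitochondrial DNA collection — 13 protein-coding (CDS), 2 rRNA and 22
tRNA genes, divergent nomenclatures, injected cross-gene mislabelings,
unannotated records and the Leucine/Serine two-locus tRNAs — without
reusing any real reference coordinates: gene order mirrors the organelle
but loci and residues are synthetic (gene regions are scaled down from
the ~1–2 kb originals to keep panels fast), and residues are random,
since the partitioning method consumes annotation only.  Every output is
a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .errors import ValidationError
from .records import AnnotatedRecord, Feature, Locus, Strand

__all__ = [
    "PanelSpec",
    "PanelTruth",
    "make_hmtdna_panel",
    "make_hmtdna_refseq",
    "make_random_trees",
]

# key, kind, length, strand, product — order mirrors the organelle's gene
# order; lengths are scaled-down but proportionate (tRNAs ~70 nt, rRNAs
# and CDS a few hundred nt)
_GENE_TABLE: tuple[tuple[str, str, int, int, str], ...] = (
    ("TRNF", "tRNA", 69, 1, "tRNA-Phe"),
    ("RNR1", "rRNA", 310, 1, "12S ribosomal RNA"),
    ("TRNV", "tRNA", 69, 1, "tRNA-Val"),
    ("RNR2", "rRNA", 560, 1, "16S ribosomal RNA"),
    ("TRNL1", "tRNA", 71, 1, "tRNA-Leu 1"),
    ("ND1", "CDS", 320, 1, "NADH dehydrogenase subunit 1"),
    ("TRNI", "tRNA", 69, 1, "tRNA-Ile"),
    ("TRNQ", "tRNA", 69, -1, "tRNA-Gln"),
    ("TRNM", "tRNA", 68, 1, "tRNA-Met"),
    ("ND2", "CDS", 340, 1, "NADH dehydrogenase subunit 2"),
    ("TRNW", "tRNA", 68, 1, "tRNA-Trp"),
    ("TRNA", "tRNA", 69, -1, "tRNA-Ala"),
    ("TRNN", "tRNA", 73, -1, "tRNA-Asn"),
    ("TRNC", "tRNA", 66, -1, "tRNA-Cys"),
    ("TRNY", "tRNA", 66, -1, "tRNA-Tyr"),
    ("COX1", "CDS", 520, 1, "cytochrome c oxidase subunit I"),
    ("TRNS1", "tRNA", 72, -1, "tRNA-Ser 1"),
    ("TRND", "tRNA", 68, 1, "tRNA-Asp"),
    ("COX2", "CDS", 230, 1, "cytochrome c oxidase subunit II"),
    ("TRNK", "tRNA", 70, 1, "tRNA-Lys"),
    ("ATP8", "CDS", 160, 1, "ATP synthase F0 subunit 8"),
    ("ATP6", "CDS", 230, 1, "ATP synthase F0 subunit 6"),
    ("COX3", "CDS", 260, 1, "cytochrome c oxidase subunit III"),
    ("TRNG", "tRNA", 68, 1, "tRNA-Gly"),
    ("ND3", "CDS", 120, 1, "NADH dehydrogenase subunit 3"),
    ("TRNR", "tRNA", 65, 1, "tRNA-Arg"),
    ("ND4L", "CDS", 100, 1, "NADH dehydrogenase subunit 4L"),
    ("ND4", "CDS", 460, 1, "NADH dehydrogenase subunit 4"),
    ("TRNH", "tRNA", 69, 1, "tRNA-His"),
    ("TRNS2", "tRNA", 59, 1, "tRNA-Ser 2"),
    ("TRNL2", "tRNA", 71, 1, "tRNA-Leu 2"),
    ("ND5", "CDS", 600, 1, "NADH dehydrogenase subunit 5"),
    ("ND6", "CDS", 170, -1, "NADH dehydrogenase subunit 6"),
    ("TRNE", "tRNA", 69, -1, "tRNA-Glu"),
    ("CYTB", "CDS", 380, 1, "cytochrome b"),
    ("TRNT", "tRNA", 66, 1, "tRNA-Thr"),
    ("TRNP", "tRNA", 68, -1, "tRNA-Pro"),
)

_SPACER = 10
_MARGIN = 20
_SUBSTITUTION_RATE = 0.002
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# split-nomenclature vocabularies for the ATP6/ATP8 genes: the two record
# halves share no value, so the term graph cannot bridge them
_SPLIT_ATP = {
    "ATP6": (("ATP6", "ATP synthase F0 subunit 6"), ("ATPase 6", "ATPase subunit 6")),
    "ATP8": (("ATP8", "ATP synthase F0 subunit 8"), ("ATPase 8", "ATPase subunit 8")),
}


@dataclass(frozen=True)
class PanelSpec:
    """Conditions for one synthetic panel."""

    n_records: int
    seed: int
    nomenclature_profile: str = "consistent"  # consistent|split_atp|per_record_mix
    mislabel_rate: float = 0.0
    unannotated_fraction: float = 0.0
    duplicate_trna_names: bool = False
    qualifier_set: str = "both"  # gene|product|both

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        for frac in (self.mislabel_rate, self.unannotated_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.nomenclature_profile not in (
            "consistent",
            "split_atp",
            "per_record_mix",
        ):
            raise ValidationError(
                f"unknown nomenclature profile {self.nomenclature_profile!r}"
            )
        if self.nomenclature_profile == "split_atp" and self.n_records < 2:
            raise ValidationError("split_atp needs at least 2 records")
        if self.qualifier_set not in ("gene", "product", "both"):
            raise ValidationError(f"unknown qualifier_set {self.qualifier_set!r}")


@dataclass(frozen=True)
class PanelTruth:
    """What the generator actually built, for oracle-style checks."""

    genes: dict[str, str] = field(default_factory=dict)  # gene key -> kind
    loci: dict[str, tuple[Locus, ...]] = field(default_factory=dict)
    names: dict[str, frozenset[str]] = field(default_factory=dict)
    unannotated_ids: tuple[str, ...] = ()
    mislabeled: tuple[tuple[str, str, str], ...] = ()  # (record, gene, product-of)

    def distinct_names(self, kind: str) -> int:
        return len({k for k, v in self.genes.items() if v == kind})


def _layout() -> dict[str, Locus]:
    loci = {}
    pos = _MARGIN
    for key, _kind, length, strand, _product in _GENE_TABLE:
        loci[key] = Locus(
            pos, pos + length, Strand.REVERSE if strand == -1 else Strand.FORWARD
        )
        pos += length + _SPACER
    return loci


def _genome_length() -> int:
    return _MARGIN + sum(g[2] + _SPACER for g in _GENE_TABLE) - _SPACER + _MARGIN


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _gene_names(spec: PanelSpec, key: str, record_index: int, rng) -> tuple[str, str]:
    """(gene qualifier value, product qualifier value) for one record."""
    kind = next(g[1] for g in _GENE_TABLE if g[0] == key)
    product = next(g[4] for g in _GENE_TABLE if g[0] == key)
    gene = key
    if spec.duplicate_trna_names and key in ("TRNL1", "TRNL2", "TRNS1", "TRNS2"):
        gene = key[:-1]  # drop the locus digit: both loci share one name
        product = product.rsplit(" ", 1)[0]
    if spec.nomenclature_profile == "split_atp" and key in _SPLIT_ATP:
        half = 0 if record_index < spec.n_records // 2 else 1
        gene, product = _SPLIT_ATP[key][half]
    elif spec.nomenclature_profile == "per_record_mix" and kind == "CDS":
        # several gene-name spellings per gene; the shared product keeps
        # the component connected, as in real GenBank panels
        variants = (gene, gene.lower(), f"MT-{gene}")
        gene = variants[int(rng.integers(0, len(variants)))]
    return gene, product


def _qualifiers(spec: PanelSpec, gene: str, product: str) -> dict[str, tuple[str, ...]]:
    quals = {}
    if spec.qualifier_set in ("gene", "both"):
        quals["gene"] = (gene,)
    if spec.qualifier_set in ("product", "both"):
        quals["product"] = (product,)
    return quals


def make_hmtdna_panel(spec: PanelSpec) -> tuple[list[AnnotatedRecord], PanelTruth]:
    """Generate a seeded annotated panel plus its ground truth.

    Each record is the panel's base genome with rare substitutions;
    unannotated records additionally carry one short deletion and one
    short insertion, so reference-guided transfer has real work to do.
    Exactly ``round(rate · n)`` records are affected by each of
    ``unannotated_fraction`` and ``mislabel_rate`` (disjoint choices,
    unannotated drawn first).
    """
    rng = np.random.default_rng([spec.seed, 0])
    base = _random_seq(np.random.default_rng([spec.seed, 1]), _genome_length())
    loci = _layout()

    n = spec.n_records
    indices = np.arange(n)
    n_unann = round(spec.unannotated_fraction * n)
    unann = set(rng.choice(indices, size=n_unann, replace=False).tolist())
    annotated = np.array([i for i in indices if i not in unann])
    n_mislabel = min(round(spec.mislabel_rate * n), len(annotated))
    mislabel = (
        set(rng.choice(annotated, size=n_mislabel, replace=False).tolist())
        if n_mislabel
        else set()
    )
    cds_keys = [g[0] for g in _GENE_TABLE if g[1] == "CDS"]
    products = {g[0]: g[4] for g in _GENE_TABLE}

    records: list[AnnotatedRecord] = []
    truth_names: dict[str, set[str]] = {g[0]: set() for g in _GENE_TABLE}
    mislabeled_log: list[tuple[str, str, str]] = []
    unannotated_ids: list[str] = []

    for i in range(n):
        rec_rng = np.random.default_rng([spec.seed, 2, i])
        seq = base.copy()
        subs = rec_rng.random(len(seq)) < _SUBSTITUTION_RATE
        if subs.any():
            shift = rec_rng.integers(1, 4, size=int(subs.sum()))
            idx = np.flatnonzero(subs)
            seq[idx] = _BASES[(np.searchsorted(_BASES, seq[idx]) + shift) % 4]
        rec_id = f"SYN{i:05d}.1"

        if i in unann:
            # indels exercise the liftover's gap handling
            del_at = int(rec_rng.integers(_MARGIN, len(seq) - _MARGIN - 3))
            ins_at = int(rec_rng.integers(_MARGIN, len(seq) - _MARGIN))
            seq = np.delete(seq, slice(del_at, del_at + 3))
            seq = np.insert(seq, ins_at, _random_seq(rec_rng, 2))
            records.append(
                AnnotatedRecord(
                    id=rec_id,
                    sequence=seq.tobytes().decode("ascii"),
                    accession=f"SYN{i:05d}",
                    description="synthetic mitochondrion, complete genome "
                    "(no annotation)",
                )
            )
            unannotated_ids.append(rec_id)
            continue

        swap: tuple[str, str] | None = None
        if i in mislabel:
            src = cds_keys[int(rec_rng.integers(0, len(cds_keys)))]
            other = [k for k in cds_keys if k != src]
            dst = other[int(rec_rng.integers(0, len(other)))]
            swap = (src, dst)
            mislabeled_log.append((rec_id, src, dst))

        features = []
        for key, kind, _length, _strand, _product in _GENE_TABLE:
            gene, product = _gene_names(spec, key, i, rec_rng)
            if swap is not None and key == swap[0]:
                product = products[swap[1]]
            truth_names[key].update({gene, product})
            quals = _qualifiers(spec, gene, product)
            features.append(Feature(kind, (loci[key],), quals))
        records.append(
            AnnotatedRecord(
                id=rec_id,
                sequence=seq.tobytes().decode("ascii"),
                accession=f"SYN{i:05d}",
                description="synthetic mitochondrion, complete genome",
                features=tuple(features),
            )
        )

    truth = PanelTruth(
        genes={g[0]: g[1] for g in _GENE_TABLE},
        loci={k: (v,) for k, v in loci.items()},
        names={k: frozenset(v) for k, v in truth_names.items()},
        unannotated_ids=tuple(unannotated_ids),
        mislabeled=tuple(mislabeled_log),
    )
    return records, truth


def make_hmtdna_refseq(seed: int) -> AnnotatedRecord:
    """The panel's reference: the unmutated base genome under the
    consistent nomenclature (the rCRS role in the real workflow)."""
    base = _random_seq(np.random.default_rng([seed, 1]), _genome_length())
    loci = _layout()
    features = tuple(
        Feature(
            kind,
            (loci[key],),
            {"gene": (key,), "product": (product,)},
        )
        for key, kind, _length, _strand, product in _GENE_TABLE
    )
    return AnnotatedRecord(
        id="SYNREF.1",
        sequence=base.tobytes().decode("ascii"),
        accession="SYNREF",
        description="synthetic mitochondrion reference, complete genome",
        features=features,
    )


# --------------------------------------------------------------------------
# random trees


def _random_topology(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Uniform random binary unrooted topology via stepwise addition:
    with a fixed label order, each topology corresponds to exactly one
    sequence of edge choices, so uniform choices give the uniform
    distribution."""
    # nodes: 0..k-1 leaves; internal nodes appended after
    k = len(labels)
    next_node = k + 1
    edges: list[list[int]] = [[0, k], [1, k], [2, k]]
    for leaf in range(3, k):
        pick = int(rng.integers(0, len(edges)))
        u, v = edges[pick]
        new = next_node
        next_node += 1
        edges[pick] = [u, new]
        edges.append([new, v])
        edges.append([new, leaf])
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def newick(node: int, parent: int) -> str:
        children = [n for n in adj[node] if n != parent]
        if not children:
            return labels[node]
        return "(" + ",".join(newick(c, node) for c in children) + ")"

    return newick(k, -1) + ";"


def make_random_trees(
    k: int, n: int, seed: int, agreement: float = 0.0
) -> dendropy.TreeList:
    """``n`` seeded trees over ``k`` shared leaves; a fraction
    ``agreement`` of them repeats one fixed topology, the rest are
    independent uniform draws."""
    if k < 4:
        raise ValidationError(f"need k >= 4 leaves, got {k}")
    if n < 1:
        raise ValidationError(f"need n >= 1 trees, got {n}")
    if not 0.0 <= agreement <= 1.0:
        raise ValidationError("agreement must lie in [0, 1]")
    labels = [f"L{i:02d}" for i in range(1, k + 1)]
    rng = np.random.default_rng([seed, 10])
    shared = _random_topology(labels, rng)
    n_shared = round(agreement * n)
    newicks = [shared] * n_shared + [
        _random_topology(labels, rng) for _ in range(n - n_shared)
    ]
    return dendropy.TreeList.get(
        data="\n".join(newicks), schema="newick", preserve_underscores=True
    )
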