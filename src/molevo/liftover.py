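"""Reference-guided annotation transfer.

An information-less sequence is globally aligned to an annotated
reference; alignment columns that introduce gaps in the reference are
deleted from the query, query deletions are padded with ``N``, and the
reference's feature loci then apply to the edited query verbatim (the
edited query has exactly the reference's length).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .records import AnnotatedRecord

__all__ = ["PairwiseAlignment", "global_align", "transfer_loci"]

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment of a reference and a query."""

    aligned_ref: str
    aligned_query: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValidationError("aligned sequences differ in length")
        if any(
            r == GAP and q == GAP
            for r, q in zip(self.aligned_ref, self.aligned_query)
        ):
            raise ValidationError("gap-gap column in alignment")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")


def global_align(
    ref: str,
    query: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> PairwiseAlignment:
    """Optimal end-to-end alignment under a linear gap penalty.

    The dynamic program is row-vectorized (the in-row dependency of a
    linear gap is a running maximum, computed as a prefix scan), so
    genome-scale pairs stay tractable.  Traceback ties are broken
    deterministically: diagonal, then gap-in-reference, then gap-in-query.
    """
    if not ref or not query:
        raise ValidationError("global_align requires two non-empty sequences")
    if gap >= 0:
        raise ValidationError("gap penalty must be negative")

    n, m = len(ref), len(query)
    r = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    cols = np.arange(m + 1, dtype=np.int32)
    score[0, :] = gap * cols
    vals = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(q == r[i - 1], match, mismatch).astype(np.int32)
        vals[0] = score[i - 1, 0] + gap
        # best way to arrive at column j without a subsequent in-row move
        np.maximum(score[i - 1, :-1] + sub, score[i - 1, 1:] + gap, out=vals[1:])
        # in-row (gap-in-ref) moves: prefix max with linear decay
        score[i, :] = np.maximum.accumulate(vals - gap * cols) + gap * cols

    aligned_ref: list[str] = []
    aligned_query: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + (
            match if ref[i - 1] == query[j - 1] else mismatch
        ):
            aligned_ref.append(ref[i - 1])
            aligned_query.append(query[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and s == score[i, j - 1] + gap:
            aligned_ref.append(GAP)
            aligned_query.append(query[j - 1])
            j -= 1
        else:
            aligned_ref.append(ref[i - 1])
            aligned_query.append(GAP)
            i -= 1
    return PairwiseAlignment(
        "".join(reversed(aligned_ref)),
        "".join(reversed(aligned_query)),
        int(score[n, m]),
    )


def transfer_loci(
    refseq: AnnotatedRecord,
    query: AnnotatedRecord,
    aln: PairwiseAlignment | None = None,
) -> AnnotatedRecord:
    """Project the reference's features onto the query.

    Columns that are gaps in the aligned reference (query insertions) are
    deleted from the query; columns that are gaps in the aligned query
    (query deletions) become ``N``.  The edited query therefore has the
    reference's length, and the reference features are copied verbatim.
    The operation is idempotent: a transferred record re-transfers to
    itself.
    """
    if not refseq.features:
        raise ValidationError("reference record carries no features")
    if aln is None:
        aln = global_align(refseq.sequence, query.sequence)
    if aln.ref != refseq.sequence or aln.query != query.sequence:
        raise ValidationError("alignment does not correspond to the given records")

    edited = []
    for rc, qc in zip(aln.aligned_ref, aln.aligned_query):
        if rc == GAP:
            continue
        edited.append("N" if qc == GAP else qc)
    return AnnotatedRecord(
        id=query.id,
        sequence="".join(edited),
        accession=query.accession,
        version=query.version,
        description=query.description,
        features=copy.deepcopy(refseq.features),
        molecule=query.molecule,
    )
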