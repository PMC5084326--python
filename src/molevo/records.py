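"""Annotated sequence records and their GenBank / FASTA boundary.

The in-memory model uses 0-based half-open coordinates throughout; the
1-based inclusive convention of GenBank flat files is converted exactly
once, at read/write time (via Biopython).  ``U`` residues are normalized
to ``T`` on read so fragment comparison works uniformly on DNA; the
original molecule alphabet is kept on the record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import IntEnum
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

__all__ = [
    "Strand",
    "Locus",
    "Feature",
    "AnnotatedRecord",
    "parse_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_fragment",
]


class Strand(IntEnum):
    """Orientation of a locus on the sequence."""

    FORWARD = 1
    REVERSE = -1


@dataclass(frozen=True, order=True)
class Locus:
    """A stranded interval, 0-based half-open.

    ``partial5``/``partial3`` carry GenBank's ``<``/``>`` markers for
    truncated feature ends.
    """

    start: int
    end: int
    strand: Strand = Strand.FORWARD
    partial5: bool = False
    partial3: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid locus [{self.start}, {self.end}): require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """A typed annotation (CDS, tRNA, rRNA, gene, ...).

    ``loci`` holds one interval per ``join`` segment, in ascending genomic
    order; ``qualifiers`` maps qualifier names to the tuple of their
    (non-empty) value strings.
    """

    kind: str
    loci: tuple[Locus, ...]
    qualifiers: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kind:
            raise ValidationError("feature kind must be non-empty")
        for name, values in self.qualifiers.items():
            if any(not v.strip() for v in values):
                raise ValidationError(f"empty value for qualifier {name!r}")

    @property
    def strand(self) -> Strand:
        return self.loci[0].strand if self.loci else Strand.FORWARD

    def values(self, names: Sequence[str] | None = None) -> list[str]:
        """All qualifier values, optionally restricted to ``names``."""
        if names is None:
            return [v for vs in self.qualifiers.values() for v in vs]
        return [v for n in names for v in self.qualifiers.get(n, ())]


@dataclass
class AnnotatedRecord:
    """One sequence with its identifier, versioned accession and features."""

    id: str
    sequence: str
    accession: str = ""
    version: int = 1
    description: str = ""
    features: tuple[Feature, ...] = ()
    molecule: str = "DNA"

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValidationError(f"record {self.id!r}: version must be >= 1")
        self.features = tuple(self.features)
        for feat in self.features:
            for locus in feat.loci:
                if locus.end > len(self.sequence):
                    raise ValidationError(
                        f"record {self.id!r}: locus [{locus.start}, {locus.end}) "
                        f"exceeds sequence length {len(self.sequence)}"
                    )

    def features_of_kind(self, kinds: Iterable[str]) -> list[Feature]:
        kinds = set(kinds)
        return [f for f in self.features if f.kind in kinds]

    def extract(self, loci: Sequence[Locus]) -> str:
        return extract_fragment(self.sequence, loci)


def extract_fragment(sequence: str, loci: Sequence[Locus]) -> str:
    """Concatenate the intervals (ascending order) and reverse-complement
    the result for reverse-strand loci — GenBank ``complement(join(...))``
    semantics."""
    if not loci:
        return ""
    ordered = sorted(loci, key=lambda l: (l.start, l.end))
    raw = "".join(sequence[l.start : l.end] for l in ordered)
    if loci[0].strand is Strand.REVERSE:
        return reverse_complement(raw)
    return raw


# --------------------------------------------------------------------------
# Biopython boundary


def _as_handle(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith((">", "LOCUS")):
            return io.StringIO(source)
        return open(source)
    return source


def _normalize_sequence(raw: str) -> tuple[str, str]:
    seq = raw.upper()
    molecule = "RNA" if "U" in seq else "DNA"
    return seq.replace("U", "T"), molecule


def _locus_from_part(part) -> Locus:
    strand = Strand.REVERSE if part.strand == -1 else Strand.FORWARD
    return Locus(
        start=int(part.start),
        end=int(part.end),
        strand=strand,
        partial5=isinstance(part.start, BeforePosition),
        partial3=isinstance(part.end, AfterPosition),
    )


def _record_from_seqrecord(sr: SeqRecord) -> AnnotatedRecord:
    sequence, molecule = _normalize_sequence(str(sr.seq))
    accessions = sr.annotations.get("accessions") or [sr.id.split(".")[0]]
    version = int(sr.annotations.get("sequence_version") or 1)
    features = []
    for f in sr.features:
        if f.location is None:
            continue
        loci = sorted(
            (_locus_from_part(p) for p in f.location.parts),
            key=lambda l: (l.start, l.end),
        )
        qualifiers = {}
        for name, values in f.qualifiers.items():
            kept = tuple(v.strip() for v in values if v and v.strip())
            if kept:
                qualifiers[name] = kept
        features.append(Feature(f.type, tuple(loci), qualifiers))
    return AnnotatedRecord(
        id=sr.id,
        sequence=sequence,
        accession=accessions[0],
        version=version,
        description=sr.description,
        features=tuple(features),
        molecule=molecule,
    )


def _seqrecord_from_record(rec: AnnotatedRecord) -> SeqRecord:
    sr = SeqRecord(
        Seq(rec.sequence),
        id=rec.id,
        name=(rec.accession or rec.id.split(".")[0])[:16],
        description=rec.description,
    )
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["accessions"] = [rec.accession or rec.id.split(".")[0]]
    sr.annotations["sequence_version"] = rec.version
    for feat in rec.features:
        parts = []
        for locus in feat.loci:
            start = BeforePosition(locus.start) if locus.partial5 else locus.start
            end = AfterPosition(locus.end) if locus.partial3 else locus.end
            parts.append(SimpleLocation(start, end, strand=int(locus.strand)))
        location = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        sr.features.append(
            SeqFeature(
                location,
                type=feat.kind,
                qualifiers={k: list(v) for k, v in feat.qualifiers.items()},
            )
        )
    return sr


def parse_genbank(source: str | IO[str]) -> list[AnnotatedRecord]:
    """Read GenBank flat-file entries into :class:`AnnotatedRecord` objects.

    Accepts a path, an open text handle, or the flat-file text itself.
    Locations are converted from 1-based inclusive to 0-based half-open,
    ``complement(...)`` becomes :attr:`Strand.REVERSE` and ``join(...)``
    a multi-interval locus list.
    """
    handle = _as_handle(source)
    try:
        seqrecords = list(SeqIO.parse(handle, "genbank"))
    except ValueError as exc:
        raise ParseError(f"malformed GenBank entry: {exc}") from exc
    return [_record_from_seqrecord(sr) for sr in seqrecords]


def write_genbank(records: Iterable[AnnotatedRecord], dest: str | IO[str]) -> None:
    """Write records as GenBank flat files (deterministic, input order)."""
    seqrecords = [_seqrecord_from_record(r) for r in records]
    if isinstance(dest, str):
        with open(dest, "w") as handle:
            SeqIO.write(seqrecords, handle, "genbank")
    else:
        SeqIO.write(seqrecords, dest, "genbank")


def read_fasta(source: str | IO[str]) -> list[AnnotatedRecord]:
    """Read FASTA into records; residues are upper-cased, ``U``→``T``.

    Duplicate identifiers are rejected with the full duplicate list.
    """
    handle = _as_handle(source)
    records: list[AnnotatedRecord] = []
    seen: dict[str, int] = {}
    for sr in SeqIO.parse(handle, "fasta"):
        seen[sr.id] = seen.get(sr.id, 0) + 1
        sequence, molecule = _normalize_sequence(str(sr.seq))
        description = sr.description
        if description.startswith(sr.id):
            description = description[len(sr.id) :].strip()
        records.append(
            AnnotatedRecord(
                id=sr.id,
                sequence=sequence,
                accession=sr.id.split(".")[0],
                description=description,
                molecule=molecule,
            )
        )
    duplicates = sorted(i for i, n in seen.items() if n > 1)
    if duplicates:
        raise ParseError(f"duplicate FASTA identifiers: {', '.join(duplicates)}")
    return records


def write_fasta(records: Iterable[AnnotatedRecord], dest: str | IO[str]) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    if isinstance(dest, str):
        with open(dest, "w") as handle:
            SeqIO.write(seqrecords, handle, "fasta")
    else:
        SeqIO.write(seqrecords, dest, "fasta")
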