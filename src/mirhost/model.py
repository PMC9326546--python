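"""Core genomic data model shared by every mirhost module.

All coordinates are 0-based, half-open ``[start, end)``; GFF3 I/O converts at
the boundary (GFF3 is 1-based, inclusive).  Objects are immutable so they can
be shared freely between the assignment, family and interpretation stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

VALID_STRANDS = ("+", "-")

#: biotype value that qualifies a gene as a potential miRNA host
PROTEIN_CODING = "protein_coding"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}: must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Full, strand-blind containment of ``other`` within ``self``."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def flipped(self) -> "GenomicInterval":
        """Same interval on the opposite strand."""
        return GenomicInterval(
            self.chrom, self.start, self.end, "-" if self.strand == "+" else "+"
        )


@dataclass(frozen=True)
class Transcript:
    """One transcript of a gene: an id plus exons sorted by start."""

    transcript_id: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons (may be empty for 1-exon transcripts)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span and one or more transcript exon chains.

    ``pseudo_exon`` marks genes that carried no exon features in the source
    annotation and were given a single flagged exon equal to their span so
    that downstream intron/exon classification still works (low confidence).
    """

    gene_id: str
    symbol: str
    biotype: str
    span: GenomicInterval
    transcripts: Tuple[Transcript, ...]
    pseudo_exon: bool = False

    def __post_init__(self) -> None:
        transcripts = tuple(
            sorted(self.transcripts, key=lambda t: t.transcript_id)
        )
        object.__setattr__(self, "transcripts", transcripts)
        if not transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in transcripts:
            for e in t.exons:
                if not self.span.contains(e):
                    raise ValueError(
                        f"gene {self.gene_id}: exon [{e.start},{e.end}) outside "
                        f"span [{self.span.start},{self.span.end})"
                    )
                if e.strand != self.span.strand:
                    raise ValueError(
                        f"gene {self.gene_id}: exon strand {e.strand} differs "
                        f"from gene strand {self.span.strand}"
                    )

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING

    def flipped(self) -> "GeneModel":
        return GeneModel(
            self.gene_id,
            self.symbol,
            self.biotype,
            self.span.flipped(),
            tuple(
                Transcript(t.transcript_id, tuple(e.flipped() for e in t.exons))
                for t in self.transcripts
            ),
            self.pseudo_exon,
        )


@dataclass(frozen=True)
class MatureMirna:
    """A processed mature product of one precursor.

    ``mature_id`` is the identifier mature products are reported under in
    expression tables (the miRBase ``Name``); sequence-indistinguishable
    paralog precursors may legitimately share it.
    """

    mature_id: str
    name: str
    span: GenomicInterval
    sequence: Optional[str] = None


@dataclass(frozen=True)
class MirnaAnnotation:
    """A precursor hairpin and the mature products derived from it."""

    precursor_id: str
    name: str
    span: GenomicInterval
    matures: Tuple[MatureMirna, ...]

    def __post_init__(self) -> None:
        matures = tuple(sorted(self.matures, key=lambda m: (m.span.start, m.span.end)))
        object.__setattr__(self, "matures", matures)
        if not matures:
            raise ValueError(f"precursor {self.precursor_id} has no mature products")
        for m in matures:
            if not self.span.contains(m.span) or m.span.strand != self.span.strand:
                raise ValueError(
                    f"mature {m.mature_id} exceeds precursor {self.precursor_id} span"
                )

    def flipped(self) -> "MirnaAnnotation":
        return MirnaAnnotation(
            self.precursor_id,
            self.name,
            self.span.flipped(),
            tuple(
                MatureMirna(m.mature_id, m.name, m.span.flipped(), m.sequence)
                for m in self.matures
            ),
        )


@dataclass(frozen=True)
class DysregulationRecord:
    """One row of a differential-expression results table."""

    feature_id: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        for label, v in (("pvalue", self.pvalue), ("padj", self.padj)):
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} {v!r} for {self.feature_id} not in [0, 1]")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc for {self.feature_id} is not finite")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.term_id} is empty")


@dataclass(frozen=True)
class GeneSetCollection:
    """A GMT-style collection of gene sets keyed by term id."""

    sets: Mapping[str, GeneSet]
    universe_hint: Optional[frozenset] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", dict(self.sets))
        if self.universe_hint is not None:
            object.__setattr__(self, "universe_hint", frozenset(self.universe_hint))

    def __len__(self) -> int:
        return len(self.sets)

    def covered_genes(self) -> frozenset:
        """Union of all member ids across the collection."""
        out: set = set()
        for s in self.sets.values():
            out |= s.members
        return frozenset(out)
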