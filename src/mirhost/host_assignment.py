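"""Genomic-context classification and host-gene assignment for miRNAs.

A miRNA is *intragenic sense* when its precursor hairpin lies fully within
the span of a protein-coding gene on the same strand; that gene is its host.
Containment by opposite-strand protein-coding genes only gives *intragenic
antisense* (no host under the sense-strand rule); everything else is
*intergenic*.  Containment by non-coding genes never assigns a host but is
recorded for audit.  When several same-strand protein-coding genes contain
the precursor (nested loci), the smallest span wins, with lexicographic
gene-id tie-break; the rest are reported as alternates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from .model import GeneModel, GenomicInterval, MirnaAnnotation

logger = logging.getLogger(__name__)

CONTEXT_SENSE = "intragenic_sense"
CONTEXT_ANTISENSE = "intragenic_antisense"
CONTEXT_INTERGENIC = "intergenic"
CONTEXTS = (CONTEXT_SENSE, CONTEXT_ANTISENSE, CONTEXT_INTERGENIC)

SUBLOC_INTRONIC = "intronic"
SUBLOC_EXONIC = "exonic"
SUBLOC_JUNCTION = "junction"
SUBLOC_NONE = "none"

DEFAULT_MAX_GAP = 10_000


@dataclass(frozen=True)
class HostAssignment:
    """The classified genomic context of one miRNA precursor."""

    precursor_id: str
    context: str
    sublocation: str
    host_gene_id: Optional[str]
    alternates: Tuple[str, ...] = ()
    confidence_flag: str = "normal"
    #: non-protein-coding genes containing the precursor (audit only)
    noncoding_containers: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.host_gene_id is not None) != (self.context == CONTEXT_SENSE):
            raise ValueError("host_gene_id present iff context is intragenic_sense")
        if (self.sublocation == SUBLOC_NONE) != (self.context == CONTEXT_INTERGENIC):
            raise ValueError("sublocation 'none' iff context is intergenic")


@dataclass(frozen=True)
class MirnaCluster:
    """A chain of >=2 precursors within ``max_gap`` on one chrom and strand."""

    cluster_id: str
    members: Tuple[str, ...]
    chrom: str
    strand: str
    span: GenomicInterval


class GeneIndex:
    """Per-chromosome interval index over gene spans for containment queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: List[GeneModel] = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.span.chrom, IntervalTree())
            tree[gene.span.start : gene.span.end] = gene

    def containing(self, interval: GenomicInterval) -> List[GeneModel]:
        """Genes whose span fully contains ``interval`` (strand-blind)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [
            iv.data
            for iv in tree.overlap(interval.start, interval.end)
            if iv.data.span.contains(interval)
        ]
        hits.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
        return hits


def resolve_nested_hosts(
    candidates: Sequence[GeneModel], mirna: MirnaAnnotation
) -> Tuple[GeneModel, Tuple[str, ...]]:
    """Pick the most specific container among >=2 candidate hosts.

    Primary = smallest span length (ties broken by lexicographic gene id);
    all other containers are returned as alternates.
    """
    ranked = sorted(candidates, key=lambda g: (g.span.length, g.gene_id))
    return ranked[0], tuple(g.gene_id for g in ranked[1:])


def _sublocation(gene: GeneModel, interval: GenomicInterval) -> str:
    """Intron/exon call of ``interval`` relative to one gene.

    Exonic if fully inside an exon of at least one transcript; otherwise
    intronic if fully inside an intron of at least one transcript; otherwise
    junction (straddles a boundary, or falls outside every transcript body,
    in every isoform).  Multi-isoform exonic/intronic disagreement resolves
    to exonic and is logged.
    """
    calls = set()
    for t in gene.transcripts:
        if any(e.contains(interval) for e in t.exons):
            calls.add(SUBLOC_EXONIC)
        elif any(i.contains(interval) for i in t.introns()):
            calls.add(SUBLOC_INTRONIC)
        else:
            calls.add(SUBLOC_JUNCTION)
    if SUBLOC_EXONIC in calls:
        if SUBLOC_INTRONIC in calls:
            logger.info(
                "gene %s: exonic/intronic isoform disagreement at "
                "[%d,%d); calling exonic",
                gene.gene_id,
                interval.start,
                interval.end,
            )
        return SUBLOC_EXONIC
    if SUBLOC_INTRONIC in calls:
        return SUBLOC_INTRONIC
    return SUBLOC_JUNCTION


def classify_context(
    mirna: MirnaAnnotation, genes: Union[GeneIndex, Sequence[GeneModel]]
) -> HostAssignment:
    """Classify one precursor against the gene models (sense-strand rule)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    containers = index.containing(mirna.span)
    coding = [g for g in containers if g.is_protein_coding]
    noncoding = tuple(
        sorted(g.gene_id for g in containers if not g.is_protein_coding)
    )
    sense = [g for g in coding if g.span.strand == mirna.span.strand]
    antisense = [g for g in coding if g.span.strand != mirna.span.strand]

    if sense:
        if len(sense) > 1:
            host, alternates = resolve_nested_hosts(sense, mirna)
        else:
            host, alternates = sense[0], ()
        return HostAssignment(
            precursor_id=mirna.precursor_id,
            context=CONTEXT_SENSE,
            sublocation=_sublocation(host, mirna.span),
            host_gene_id=host.gene_id,
            alternates=alternates,
            confidence_flag="pseudo_exon_gene" if host.pseudo_exon else "normal",
            noncoding_containers=noncoding,
        )
    if antisense:
        # no host under the sense-strand rule; classify sublocation against
        # the most specific antisense container for audit purposes
        ref, _ = (
            resolve_nested_hosts(antisense, mirna)
            if len(antisense) > 1
            else (antisense[0], ())
        )
        return HostAssignment(
            precursor_id=mirna.precursor_id,
            context=CONTEXT_ANTISENSE,
            sublocation=_sublocation(ref, mirna.span),
            host_gene_id=None,
            alternates=tuple(sorted(g.gene_id for g in antisense)),
            confidence_flag="pseudo_exon_gene" if ref.pseudo_exon else "normal",
            noncoding_containers=noncoding,
        )
    return HostAssignment(
        precursor_id=mirna.precursor_id,
        context=CONTEXT_INTERGENIC,
        sublocation=SUBLOC_NONE,
        host_gene_id=None,
        noncoding_containers=noncoding,
    )


def classify_all(
    mirnas: Iterable[MirnaAnnotation], genes: Union[GeneIndex, Sequence[GeneModel]]
) -> Dict[str, HostAssignment]:
    """Classify every precursor; returns a precursor_id -> assignment map."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if not index.genes:
        logger.warning("empty gene list: every miRNA will be intergenic")
    return {m.precursor_id: classify_context(m, index) for m in mirnas}


def detect_clusters(
    mirnas: Iterable[MirnaAnnotation], max_gap: int = DEFAULT_MAX_GAP
) -> List[MirnaCluster]:
    """Single-linkage chaining of precursors on one chrom and strand.

    Two precursors chain when the gap between their spans is <= ``max_gap``
    (overlap counts as gap 0).  Singletons are not reported.  Output is
    invariant to the input ordering of miRNAs.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_key: Dict[Tuple[str, str], List[MirnaAnnotation]] = {}
    for m in mirnas:
        by_key.setdefault((m.span.chrom, m.span.strand), []).append(m)

    clusters: List[MirnaCluster] = []
    for (chrom, strand) in sorted(by_key):
        members = sorted(by_key[(chrom, strand)], key=lambda m: (m.span.start, m.span.end))
        chain: List[MirnaAnnotation] = []
        chain_end = None
        for m in members + [None]:  # sentinel flushes the last chain
            if m is not None and (chain_end is None or m.span.start - chain_end <= max_gap):
                chain.append(m)
                chain_end = max(chain_end or m.span.end, m.span.end)
                continue
            if len(chain) >= 2:
                clusters.append(
                    MirnaCluster(
                        cluster_id=f"cluster:{chrom}:{strand}:{len(clusters) + 1}",
                        members=tuple(c.precursor_id for c in chain),
                        chrom=chrom,
                        strand=strand,
                        span=GenomicInterval(
                            chrom, chain[0].span.start, chain_end, strand
                        ),
                    )
                )
            if m is not None:
                chain, chain_end = [m], m.span.end
    return clusters


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def assignments_to_tsv(assignments: Iterable[HostAssignment]) -> str:
    lines = ["precursor_id\tcontext\tsublocation\thost_gene_id\talternates\tconfidence_flag"]
    for a in assignments:
        lines.append(
            "\t".join(
                [
                    a.precursor_id,
                    a.context,
                    a.sublocation,
                    a.host_gene_id or ".",
                    ",".join(a.alternates) or ".",
                    a.confidence_flag,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def clusters_to_tsv(clusters: Iterable[MirnaCluster]) -> str:
    lines = ["cluster_id\tchrom\tstrand\tstart\tend\tmembers"]
    for c in clusters:
        lines.append(
            f"{c.cluster_id}\t{c.chrom}\t{c.strand}\t{c.span.start}\t{c.span.end}\t"
            + ",".join(c.members)
        )
    return "\n".join(lines) + "\n"


_BED_COLOR = {
    CONTEXT_SENSE: "0,128,0",
    CONTEXT_ANTISENSE: "255,140,0",
    CONTEXT_INTERGENIC: "128,128,128",
}


def precursors_to_bed(
    mirnas: Iterable[MirnaAnnotation], assignments: Dict[str, HostAssignment]
) -> str:
    """BED export of precursors with itemRgb colouring by context."""
    lines = []
    for m in sorted(mirnas, key=lambda m: (m.span.chrom, m.span.start)):
        a = assignments[m.precursor_id]
        s = m.span
        lines.append(
            f"{s.chrom}\t{s.start}\t{s.end}\t{m.precursor_id}|{a.context}\t0\t"
            f"{s.strand}\t{s.start}\t{s.end}\t{_BED_COLOR[a.context]}"
        )
    return "\n".join(lines) + "\n"
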