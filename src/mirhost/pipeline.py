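"""End-to-end orchestration of the host-gene interpretation workflow.

Order of operations: classify every precursor against the gene models,
detect clusters (audit), group sequence-indistinguishable matures, select
dysregulated miRNAs from the DE table, expand them to the deduplicated
host-gene set, quantify co-dysregulation against the gene DE table, and run
host-mode (and optionally target-mode) over-representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from . import annotation_io as aio
from .enrichment import (
    EnrichmentResult,
    enrich,
    enrichment_to_tsv,
    target_set_enrichment,
)
from .family_logic import (
    FamilyGroup,
    group_indistinguishable_matures,
    provenance_to_tsv,
)
from .host_assignment import (
    CONTEXT_SENSE,
    DEFAULT_MAX_GAP,
    HostAssignment,
    MirnaCluster,
    assignments_to_tsv,
    classify_all,
    clusters_to_tsv,
    detect_clusters,
)
from .interpretation import (
    CoDysregulationReport,
    HostGeneSet,
    build_host_gene_set,
    co_dysregulation_report,
    codysregulation_to_tsv,
    host_gene_set_to_tsv,
    render_codysregulation,
    select_dysregulated,
)
from .model import (
    DysregulationRecord,
    GeneModel,
    GeneSetCollection,
    MirnaAnnotation,
)

UNIVERSE_GMT_COVERED = "gmt-covered"
UNIVERSE_HOST_CAPABLE = "host-capable"


@dataclass
class PipelineResult:
    assignments: Dict[str, HostAssignment]
    clusters: List[MirnaCluster]
    groups: List[FamilyGroup]
    selected_mirnas: Dict[str, str]
    host_set: HostGeneSet
    codysregulation: Optional[CoDysregulationReport]
    enrichment_host: List[EnrichmentResult]
    enrichment_target: List[EnrichmentResult]
    target_unmapped: List[str]
    universe: List[str]

    def write(self, outdir, mirnas: Optional[Sequence[MirnaAnnotation]] = None) -> None:
        """Write the TSV/markdown report bundle (deterministic content)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        order = (
            [m.precursor_id for m in mirnas]
            if mirnas is not None
            else sorted(self.assignments)
        )
        (out / "assignments.tsv").write_text(
            assignments_to_tsv(self.assignments[p] for p in order)
        )
        (out / "clusters.tsv").write_text(clusters_to_tsv(self.clusters))
        (out / "family_provenance.tsv").write_text(
            provenance_to_tsv(
                self.groups,
                [(g, p, m) for g, p, m, _ in self.host_set.provenance],
            )
        )
        (out / "host_gene_set.tsv").write_text(host_gene_set_to_tsv(self.host_set))
        if self.codysregulation is not None:
            (out / "codysregulation.tsv").write_text(
                codysregulation_to_tsv(self.codysregulation)
            )
            (out / "summary.md").write_text(
                render_codysregulation(self.codysregulation)
            )
        (out / "enrichment_host.tsv").write_text(
            enrichment_to_tsv(self.enrichment_host)
        )
        if self.enrichment_target:
            (out / "enrichment_target.tsv").write_text(
                enrichment_to_tsv(self.enrichment_target)
            )
        if self.host_set.unmapped or self.target_unmapped:
            (out / "unmapped.txt").write_text(
                "\n".join(
                    [f"host\t{m}" for m in self.host_set.unmapped]
                    + [f"target\t{m}" for m in self.target_unmapped]
                )
                + "\n"
            )


def build_universe(
    genes: Sequence[GeneModel],
    collection: Optional[GeneSetCollection],
    assignments: Mapping[str, HostAssignment],
    mode: str = UNIVERSE_GMT_COVERED,
) -> List[str]:
    """Background gene universe for host-mode enrichment.

    ``gmt-covered``: protein-coding genes of the annotation that appear in
    at least one gene-set term.  ``host-capable``: further restricted to
    genes that host at least one annotated miRNA, which controls for the
    bias that only miRNA-hosting genes can ever enter a host-gene query.
    """
    coding = {g.gene_id for g in genes if g.is_protein_coding}
    if collection is not None:
        coding &= collection.covered_genes()
    if mode == UNIVERSE_HOST_CAPABLE:
        capable = {
            a.host_gene_id for a in assignments.values() if a.context == CONTEXT_SENSE
        }
        coding &= capable
    elif mode != UNIVERSE_GMT_COVERED:
        raise ValueError(f"unknown universe mode {mode!r}")
    return sorted(coding)


def run_pipeline(
    genes: Sequence[GeneModel],
    mirnas: Sequence[MirnaAnnotation],
    mirna_de: Sequence[DysregulationRecord],
    gene_de: Optional[Sequence[DysregulationRecord]] = None,
    sequences: Optional[Mapping[str, str]] = None,
    collection: Optional[GeneSetCollection] = None,
    target_map: Optional[Mapping[str, Set[str]]] = None,
    padj_threshold: float = 0.1,
    min_abs_log2fc: float = 0.0,
    max_gap: int = DEFAULT_MAX_GAP,
    universe: Optional[Iterable[str]] = None,
    universe_mode: str = UNIVERSE_GMT_COVERED,
) -> PipelineResult:
    """Run the whole host-gene interpretation workflow on in-memory inputs."""
    assignments = classify_all(mirnas, genes)
    clusters = detect_clusters(mirnas, max_gap=max_gap)
    groups = group_indistinguishable_matures(mirnas, sequences)
    selected = select_dysregulated(mirna_de, padj_threshold, min_abs_log2fc)
    host_set = build_host_gene_set(selected, groups, assignments)

    codys = None
    if gene_de is not None:
        dys_genes = select_dysregulated(gene_de, padj_threshold)
        tested_genes = {r.feature_id for r in gene_de}
        universe_size = len(tested_genes | set(host_set.gene_ids))
        codys = co_dysregulation_report(
            host_set.intragenic_pairs(), dys_genes.keys(), universe_size
        )

    uni: List[str] = []
    enr_host: List[EnrichmentResult] = []
    enr_target: List[EnrichmentResult] = []
    target_unmapped: List[str] = []
    if collection is not None:
        uni = (
            sorted(set(universe))
            if universe is not None
            else build_universe(genes, collection, assignments, universe_mode)
        )
        if host_set.gene_ids:
            enr_host = enrich(host_set.gene_ids, collection, uni)
        if target_map is not None:
            enr_target, target_unmapped = target_set_enrichment(
                selected.keys(), target_map, collection, uni
            )
    return PipelineResult(
        assignments=assignments,
        clusters=clusters,
        groups=groups,
        selected_mirnas=selected,
        host_set=host_set,
        codysregulation=codys,
        enrichment_host=enr_host,
        enrichment_target=enr_target,
        target_unmapped=target_unmapped,
        universe=uni,
    )


def run_pipeline_from_files(
    genes_gff3,
    mirnas_gff3,
    mirna_de_tsv,
    gene_de_tsv=None,
    sequences_tsv=None,
    gmt=None,
    target_map_tsv=None,
    universe_file=None,
    **kwargs,
) -> Tuple[PipelineResult, List[MirnaAnnotation]]:
    """File-based front end of :func:`run_pipeline` (paths or file-likes)."""
    genes = aio.parse_gene_models(genes_gff3)
    mirnas = aio.parse_mirna_annotations(mirnas_gff3)
    mirna_de = aio.parse_de_table(mirna_de_tsv)
    gene_de = aio.parse_de_table(gene_de_tsv) if gene_de_tsv is not None else None
    sequences = (
        aio.parse_sequence_table(sequences_tsv) if sequences_tsv is not None else None
    )
    collection = aio.parse_gmt(gmt) if gmt is not None else None
    target_map = (
        aio.parse_target_map(target_map_tsv) if target_map_tsv is not None else None
    )
    universe = None
    if universe_file is not None:
        text = universe_file.read() if hasattr(universe_file, "read") else Path(
            universe_file
        ).read_text()
        universe = [line.strip() for line in text.splitlines() if line.strip()]
    result = run_pipeline(
        genes,
        mirnas,
        mirna_de,
        gene_de=gene_de,
        sequences=sequences,
        collection=collection,
        target_map=target_map,
        universe=universe,
        **kwargs,
    )
    return result, mirnas
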