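"""Dysregulation selection, host-gene set construction and co-dysregulation.

The selection rule is the strict adjusted-p criterion padj < threshold
(default 0.1) with an optional absolute log2 fold-change floor.  The host
gene set is the family-expanded union of sense-strand hosts over all
selected matures; set semantics make a clustered group of co-hosted miRNAs
contribute their shared host only once.  The co-dysregulation report counts
*miRNAs* whose host gene is itself dysregulated — a dysregulated host
carrying two dysregulated miRNAs contributes two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .enrichment import hypergeom_upper_tail
from .family_logic import FamilyGroup, expand_family_hosts
from .host_assignment import HostAssignment
from .model import DysregulationRecord

logger = logging.getLogger(__name__)

DEFAULT_PADJ_THRESHOLD = 0.1

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_FLAT = "none"


def select_dysregulated(
    records: Iterable[DysregulationRecord],
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
    min_abs_log2fc: float = 0.0,
) -> Dict[str, str]:
    """Feature ids with padj strictly below the threshold, with direction.

    Returns ``feature_id -> 'up' | 'down' | 'none'`` (sign of log2fc).  The
    inequality is strict: padj exactly at the threshold is not selected.
    """
    if not (0.0 < padj_threshold <= 1.0):
        raise ValueError("padj_threshold must lie in (0, 1]")
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    selected: Dict[str, str] = {}
    for r in records:
        if r.padj < padj_threshold and abs(r.log2fc) >= min_abs_log2fc:
            if r.log2fc > 0:
                selected[r.feature_id] = DIRECTION_UP
            elif r.log2fc < 0:
                selected[r.feature_id] = DIRECTION_DOWN
            else:
                selected[r.feature_id] = DIRECTION_FLAT
    if not selected:
        logger.warning("no feature passed padj < %g", padj_threshold)
    return selected


@dataclass(frozen=True)
class HostGeneSet:
    """Deduplicated host genes of the selected miRNAs, with provenance."""

    gene_ids: frozenset
    #: (host_gene_id, precursor_id, mature_id, direction) per contribution
    provenance: Tuple[Tuple[str, str, str, str], ...]
    n_dysregulated_mirnas: int
    n_intragenic_dysregulated: int
    unmapped: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gene_ids != frozenset(p[0] for p in self.provenance):
            raise ValueError("gene_ids inconsistent with provenance")

    def intragenic_pairs(self) -> List[Tuple[str, str]]:
        """Distinct (mature_id, host_gene_id) pairs for co-dysregulation."""
        return sorted({(mid, gene) for gene, _, mid, _ in self.provenance})


def build_host_gene_set(
    selected: Mapping[str, str],
    groups: Iterable[FamilyGroup],
    assignments: Mapping[str, HostAssignment],
) -> HostGeneSet:
    """Family-expanded union of sense-strand hosts over selected matures.

    ``selected`` maps mature ids to their direction of dysregulation (the
    output of :func:`select_dysregulated` on the miRNA DE table).  The
    result is order-invariant and idempotent by construction.
    """
    groups = list(groups)
    expansion = expand_family_hosts(selected.keys(), groups, assignments)
    provenance = tuple(
        (gene, prec, mid, selected[mid])
        for gene, prec, mid in sorted(expansion.provenance, key=lambda r: (r[2], r[1]))
    )
    intragenic_matures = {mid for _, _, mid, _ in provenance}
    return HostGeneSet(
        gene_ids=frozenset(expansion.gene_ids),
        provenance=provenance,
        n_dysregulated_mirnas=len(selected),
        n_intragenic_dysregulated=len(intragenic_matures),
        unmapped=tuple(expansion.unmapped),
    )


@dataclass(frozen=True)
class CoDysregulationReport:
    """Overlap between dysregulated miRNAs' hosts and dysregulated genes.

    ``overlap_pvalue`` (upper-tail hypergeometric on the distinct host
    genes against the dysregulated-gene list) is an added audit statistic,
    not part of the original host-gene procedure.
    """

    n_intragenic: int
    n_codys: int
    fraction: Optional[float]
    overlap_pvalue: float
    codysregulated_mirnas: Tuple[str, ...] = ()
    codysregulated_hosts: Tuple[str, ...] = ()

    @property
    def percent_text(self) -> str:
        if self.fraction is None:
            return "NA"
        return f"{100.0 * self.fraction:.1f}%"


def co_dysregulation_report(
    pairs: Iterable[Tuple[str, str]],
    dysregulated_gene_ids: Iterable[str],
    universe_size: int,
) -> CoDysregulationReport:
    """Quantify miRNA/host-gene co-dysregulation.

    ``pairs`` are (mirna_id, host_gene_id) pairs for the selected intragenic
    miRNAs (a family-expanded miRNA may appear with several hosts).  A miRNA
    counts as co-dysregulated when any of its hosts is in the
    dysregulated-gene list.  ``universe_size`` is the number of genes the
    dysregulated-gene list was drawn from.
    """
    by_mirna: Dict[str, Set[str]] = {}
    for mid, gene in pairs:
        by_mirna.setdefault(mid, set()).add(gene)
    dys = set(dysregulated_gene_ids)

    n_intragenic = len(by_mirna)
    codys = sorted(m for m, hosts in by_mirna.items() if hosts & dys)
    hosts_all: Set[str] = set().union(*by_mirna.values()) if by_mirna else set()
    hosts_dys = sorted(hosts_all & dys)

    if universe_size < max(len(dys), len(hosts_all), 1):
        raise ValueError(
            f"universe_size {universe_size} smaller than the overlap inputs"
        )
    pvalue = (
        hypergeom_upper_tail(len(hosts_dys), len(dys), len(hosts_all), universe_size)
        if hosts_all
        else 1.0
    )
    return CoDysregulationReport(
        n_intragenic=n_intragenic,
        n_codys=len(codys),
        fraction=(len(codys) / n_intragenic) if n_intragenic else None,
        overlap_pvalue=pvalue,
        codysregulated_mirnas=tuple(codys),
        codysregulated_hosts=tuple(hosts_dys),
    )


def render_codysregulation(report: CoDysregulationReport) -> str:
    """Plain-text/markdown summary of the co-dysregulation report."""
    lines = [
        "# miRNA / host-gene co-dysregulation",
        "",
        f"- intragenic dysregulated miRNAs considered: {report.n_intragenic}",
        f"- with a dysregulated host gene: {report.n_codys} ({report.percent_text})",
        f"- dysregulated host genes: "
        + (", ".join(report.codysregulated_hosts) or "none"),
        f"- host/dysregulated-gene overlap p (hypergeometric upper tail; "
        f"audit statistic): {report.overlap_pvalue:.3g}",
        "",
    ]
    return "\n".join(lines)


def codysregulation_to_tsv(report: CoDysregulationReport) -> str:
    lines = [
        "n_intragenic\tn_codys\tpercent\toverlap_pvalue\tcodys_mirnas\tcodys_hosts",
        "\t".join(
            [
                str(report.n_intragenic),
                str(report.n_codys),
                report.percent_text,
                f"{report.overlap_pvalue:.6g}",
                ",".join(report.codysregulated_mirnas) or ".",
                ",".join(report.codysregulated_hosts) or ".",
            ]
        ),
    ]
    return "\n".join(lines) + "\n"


def host_gene_set_to_tsv(host_set: HostGeneSet) -> str:
    lines = ["host_gene_id\tprecursor_id\tmature_id\tdirection"]
    for gene, prec, mid, direction in host_set.provenance:
        lines.append(f"{gene}\t{prec}\t{mid}\t{direction}")
    return "\n".join(lines) + "\n"
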