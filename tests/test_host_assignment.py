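"""Context classification, nested-host resolution and cluster detection."""

import pytest

from mirhost.host_assignment import (
    CONTEXT_ANTISENSE,
    CONTEXT_INTERGENIC,
    CONTEXT_SENSE,
    GeneIndex,
    classify_all,
    classify_context,
    detect_clusters,
    resolve_nested_hosts,
)
from mirhost.model import (
    GeneModel,
    GenomicInterval,
    MatureMirna,
    MirnaAnnotation,
    Transcript,
)
from mirhost.synthetic_data import generate
from conftest import small_sim_config


def make_gene(gene_id, start, end, strand="+", biotype="protein_coding",
              exons=None, chrom="chr1"):
    if exons is None:
        exons = [(start, start + 200), (end - 200, end)]
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel(
        gene_id, gene_id, biotype,
        GenomicInterval(chrom, start, end, strand),
        (Transcript(f"{gene_id}.t1", ivs),),
    )


def make_mirna(pid, start, end, strand="+", chrom="chr1"):
    return MirnaAnnotation(
        pid, pid, GenomicInterval(chrom, start, end, strand),
        (MatureMirna(f"{pid}-3p", f"{pid}-3p",
                     GenomicInterval(chrom, start + 5, start + 27, strand)),),
    )


def brute_force_classify(mirna, genes):
    """Independent O(n*m) containment scan (no interval index)."""
    containers = [
        g for g in genes
        if g.span.chrom == mirna.span.chrom
        and g.span.start <= mirna.span.start
        and mirna.span.end <= g.span.end
    ]
    coding = [g for g in containers if g.biotype == "protein_coding"]
    sense = [g for g in coding if g.span.strand == mirna.span.strand]
    anti = [g for g in coding if g.span.strand != mirna.span.strand]
    if sense:
        host = sorted(sense, key=lambda g: (g.span.length, g.gene_id))[0]
        return (CONTEXT_SENSE, host.gene_id)
    if anti:
        return (CONTEXT_ANTISENSE, None)
    return (CONTEXT_INTERGENIC, None)


class TestClassifyContext:
    def test_intronic_sense_host_pank3_style(self, fixture_bundle):
        res = classify_all(fixture_bundle.mirnas, fixture_bundle.genes)
        a = res["mir-103a-1"]
        assert (a.context, a.sublocation, a.host_gene_id) == (
            CONTEXT_SENSE, "intronic", "PANK3",
        )
        assert res["mir-1307"].sublocation == "exonic"

    def test_downstream_precursor_is_intergenic(self):
        gene = make_gene("G1", 1000, 5000)
        a = classify_context(make_mirna("m", 5500, 5600), [gene])
        assert (a.context, a.sublocation, a.host_gene_id) == (
            CONTEXT_INTERGENIC, "none", None,
        )

    def test_opposite_strand_container_is_antisense_without_host(self):
        gene = make_gene("G1", 1000, 5000, strand="+")
        a = classify_context(make_mirna("m", 2000, 2100, strand="-"), [gene])
        assert a.context == CONTEXT_ANTISENSE
        assert a.host_gene_id is None
        assert a.alternates == ("G1",)

    def test_noncoding_container_counts_as_intergenic_but_audited(self):
        linc = make_gene("LINC1", 1000, 5000, biotype="lincRNA")
        a = classify_context(make_mirna("m", 2000, 2100), [linc])
        assert a.context == CONTEXT_INTERGENIC
        assert a.noncoding_containers == ("LINC1",)

    def test_partial_edge_overlap_is_not_embedded(self):
        gene = make_gene("G1", 1000, 5000)
        a = classify_context(make_mirna("m", 4950, 5050), [gene])
        assert a.context == CONTEXT_INTERGENIC

    def test_pseudo_exon_gene_flagged_low_confidence(self):
        gene = GeneModel(
            "G1", "G1", "protein_coding",
            GenomicInterval("chr1", 1000, 5000, "+"),
            (Transcript("G1.pseudo", (GenomicInterval("chr1", 1000, 5000, "+"),)),),
            pseudo_exon=True,
        )
        a = classify_context(make_mirna("m", 2000, 2100), [gene])
        assert a.confidence_flag == "pseudo_exon_gene"
        assert a.sublocation == "exonic"

    def test_exonic_wins_over_intronic_across_isoforms(self):
        # isoform 1: miRNA inside an intron; isoform 2: inside a long exon
        t1 = Transcript("t1", (
            GenomicInterval("chr1", 1000, 1200, "+"),
            GenomicInterval("chr1", 3000, 3200, "+"),
        ))
        t2 = Transcript("t2", (GenomicInterval("chr1", 1000, 3200, "+"),))
        gene = GeneModel("G1", "G1", "protein_coding",
                         GenomicInterval("chr1", 1000, 3200, "+"), (t1, t2))
        a = classify_context(make_mirna("m", 2000, 2100), [gene])
        assert a.sublocation == "exonic"

    def test_junction_when_straddling_boundary_in_every_isoform(self):
        gene = make_gene("G1", 1000, 5000, exons=[(1000, 1500), (4000, 5000)])
        a = classify_context(make_mirna("m", 1450, 1550), [gene])
        assert a.sublocation == "junction"

    def test_empty_gene_list_everything_intergenic(self):
        res = classify_all([make_mirna("m", 10, 100)], [])
        assert res["m"].context == CONTEXT_INTERGENIC


class TestNestedHosts:
    def test_smallest_span_is_primary(self):
        outer = make_gene("BIG", 1000, 301_000, exons=[(1000, 2000), (300_000, 301_000)])
        inner = make_gene("SMALL", 10_000, 60_000,
                          exons=[(10_000, 10_500), (59_000, 60_000)])
        host, alts = resolve_nested_hosts([outer, inner], make_mirna("m", 20_000, 20_100))
        assert host.gene_id == "SMALL"
        assert alts == ("BIG",)

    def test_tie_broken_lexicographically(self):
        a = make_gene("GENEA", 1000, 5000)
        b = make_gene("GENEB", 1000, 5000)
        host, _ = resolve_nested_hosts([b, a], make_mirna("m", 2000, 2100))
        assert host.gene_id == "GENEA"

    def test_three_containers_give_two_alternates(self):
        genes = [
            make_gene("G1", 0, 100_000, exons=[(0, 100), (99_900, 100_000)]),
            make_gene("G2", 1000, 50_000, exons=[(1000, 1100), (49_900, 50_000)]),
            make_gene("G3", 2000, 30_000, exons=[(2000, 2100), (29_900, 30_000)]),
        ]
        host, alts = resolve_nested_hosts(genes, make_mirna("m", 10_000, 10_100))
        assert host.gene_id == "G3"
        assert len(alts) == 2


class TestProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_partition_every_mirna_has_exactly_one_context(self, seed):
        bundle = generate(small_sim_config(seed))
        res = classify_all(bundle.mirnas, bundle.genes)
        assert len(res) == len(bundle.mirnas)
        counts = {c: 0 for c in (CONTEXT_SENSE, CONTEXT_ANTISENSE, CONTEXT_INTERGENIC)}
        for a in res.values():
            counts[a.context] += 1
        assert sum(counts.values()) == len(bundle.mirnas)

    @pytest.mark.parametrize("seed", range(6))
    def test_strand_flip_swaps_sense_and_antisense(self, seed):
        bundle = generate(small_sim_config(100 + seed))
        flipped_genes = [g.flipped() for g in bundle.genes]
        for m in bundle.mirnas:
            orig = classify_context(m, bundle.genes)
            # flip miRNA only: sense <-> antisense, intergenic fixed
            swapped = classify_context(m.flipped(), bundle.genes)
            both = classify_context(m.flipped(), flipped_genes)
            mapping = {
                CONTEXT_SENSE: CONTEXT_ANTISENSE,
                CONTEXT_ANTISENSE: CONTEXT_SENSE,
                CONTEXT_INTERGENIC: CONTEXT_INTERGENIC,
            }
            assert swapped.context == mapping[orig.context]
            assert both.context == orig.context

    @pytest.mark.parametrize("seed", range(5))
    def test_index_agrees_with_brute_force_scan(self, seed):
        bundle = generate(small_sim_config(200 + seed))
        index = GeneIndex(bundle.genes)
        for m in bundle.mirnas:
            a = classify_context(m, index)
            context, host = brute_force_classify(m, bundle.genes)
            assert (a.context, a.host_gene_id) == (context, host)


class TestClusters:
    def test_singleton_not_reported(self):
        mirnas = [make_mirna("a", 1000, 1100), make_mirna("b", 2_000_000, 2_000_100)]
        assert detect_clusters(mirnas, max_gap=10_000) == []

    def test_pair_within_gap_forms_cluster(self):
        mirnas = [make_mirna("a", 1000, 1100), make_mirna("b", 3100, 3200)]
        (c,) = detect_clusters(mirnas, max_gap=10_000)
        assert c.members == ("a", "b")
        assert (c.span.start, c.span.end) == (1000, 3200)

    def test_single_linkage_chains_three(self):
        # A-(6kb)-B-(6kb)-C with max_gap 10kb: one cluster of three, as the
        # brute-force pairwise chaining oracle gives
        mirnas = [
            make_mirna("A", 0, 100),
            make_mirna("B", 6100, 6200),
            make_mirna("C", 12_300, 12_400),
        ]
        assert _oracle_chain(mirnas, 10_000) == [["A", "B", "C"]]
        (c,) = detect_clusters(mirnas, max_gap=10_000)
        assert c.members == ("A", "B", "C")

    def test_strand_and_chrom_separate_chains(self):
        mirnas = [
            make_mirna("a", 1000, 1100, strand="+"),
            make_mirna("b", 2000, 2100, strand="-"),
        ]
        assert detect_clusters(mirnas, max_gap=10_000) == []

    def test_output_invariant_to_input_order(self):
        mirnas = [
            make_mirna("a", 1000, 1100),
            make_mirna("b", 3000, 3100),
            make_mirna("c", 500_000, 500_100),
            make_mirna("d", 504_000, 504_100),
        ]
        fwd = detect_clusters(mirnas, max_gap=10_000)
        rev = detect_clusters(list(reversed(mirnas)), max_gap=10_000)
        assert fwd == rev


def _oracle_chain(mirnas, max_gap):
    """Brute-force transitive closure over pairwise gap <= max_gap."""
    ms = sorted(mirnas, key=lambda m: m.span.start)
    groups = [[m] for m in ms]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    a.span.chrom == b.span.chrom
                    and a.span.strand == b.span.strand
                    and max(a.span.start, b.span.start)
                    - min(a.span.end, b.span.end)
                    <= max_gap
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i].extend(groups[j])
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return sorted(
        sorted(m.precursor_id for m in g) for g in groups if len(g) >= 2
    )
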