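# Methods

## Background and model

Most mature miRNAs are processed from precursor hairpins that lie inside
protein-coding genes, usually within introns, and intragenic miRNAs are
frequently co-expressed — and in disease, co-dysregulated — with the gene
that hosts them.  `mirhost` operationalises a host-gene-based reading of a
dysregulated miRNA list: instead of pooling thousands of noisy predicted
target genes, it maps each dysregulated miRNA to its single, unambiguous
host gene and interprets that compact gene list by over-representation
analysis.  A target-gene mode is retained purely for side-by-side
comparison.

The procedure is:

1. **Host assignment.**  A precursor is *intragenic sense* when its span is
   fully contained in the span of a protein-coding gene on the same strand;
   that gene is the host.  Containment only by opposite-strand coding genes
   gives *intragenic antisense* (no host); everything else is *intergenic*.
   Sub-location is *exonic* if the precursor sits wholly inside an exon of
   at least one transcript, *intronic* if wholly inside an intron of at
   least one transcript and exonic in none, and *junction* otherwise.
2. **Family collapsing.**  Mature miRNAs with exactly identical sequences
   (duplicated precursors such as mir-103a-1/mir-103a-2) cannot be
   distinguished by sequencing; a detected dysregulated mature is credited
   to every precursor in its sequence-identity group, hence to every host
   gene any of them occupies.
3. **Selection.**  Dysregulated features are those with adjusted p strictly
   below the threshold (default 0.1); no fold-change floor by default.
4. **Host-gene set.**  The family-expanded union of hosts over all selected
   matures.  Because the result is a set, a cluster of co-hosted miRNAs
   contributes its shared host exactly once.
5. **Co-dysregulation.**  Among selected intragenic miRNAs, the fraction
   whose host gene is itself in the dysregulated-gene list (the counting
   unit is the miRNA: a dysregulated host with two dysregulated miRNAs
   counts twice).  An upper-tail hypergeometric p for the host/dysregulated
   gene overlap is attached as an audit statistic; it is not part of the
   original procedure.
6. **Enrichment.**  One-sided hypergeometric over-representation of the
   host set against a GMT collection, BH-adjusted across terms.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `padj_threshold` | 0.1 | strict adjusted-p selection cut (miRNA and gene DE) |
| `min_abs_log2fc` | 0 | optional absolute log2 fold-change floor |
| `max_gap` | 10 kb | single-linkage chaining gap for cluster reporting |
| `min_term_size` / `max_term_size` | 3 / 2000 | term-size band tested, after universe intersection |
| universe mode | `gmt-covered` | protein-coding genes present in ≥1 term; `host-capable` restricts to genes hosting ≥1 annotated miRNA |

The `host-capable` universe controls the selection bias that only
miRNA-hosting genes can ever enter a host-gene query; with a generic
background, terms rich in host-capable genes are slightly favoured.  The
choice materially shifts p-values, so it is an explicit flag rather than a
hidden default.

## Conventions and tie-breaks

- Internal coordinates are 0-based half-open; GFF3 converts at the I/O
  boundary only.
- Classification uses the precursor interval, not the matures: host
  relationships are defined at hairpin level and matures are
  sub-intervals, so calls differ only at containment boundaries.
- "Embedded" means full containment; a precursor straddling a gene edge is
  intergenic.
- Nested same-strand coding containers resolve to the smallest span
  (most specific locus), ties broken by lexicographic gene id; losers are
  reported as alternates.
- A miRNA exonic in one isoform and intronic in another is called exonic
  (any-transcript-exonic wins) and the disagreement is logged.
- Mature identifiers are the miRBase-style names that expression tables
  report; sequence-identical paralogs may share one (that sharing is what
  makes family expansion reach several hosts from one detected feature).
  The -5p and -3p products of one precursor are never merged.
- Genes without exon features are kept with a flagged pseudo-exon equal to
  their span; assignments against them carry `pseudo_exon_gene` confidence.
- Enrichment output is sorted by (p, term id); all writers emit sorted,
  fixed-format text so identical inputs give byte-identical reports.
- BH adjustment is the step-up `q_(i) = min_{j>=i} m p_(j)/j`, clipped at 1
  and returned in input order.  Note BH is not idempotent: re-adjusting
  already-adjusted values can increase them (e.g. p = (0.25, 1.0) gives
  q = (0.5, 1.0), which re-adjusts to (1.0, 1.0)).

## Synthetic data

The generator emits a complete study in plain text (gene GFF3, miRBase-style
miRNA GFF3, mature-sequence table, miRNA and gene DE tables, GMT, target
map, universe list) plus `truth.json`.  Defaults mirror the motivating
study's structure: 71 dysregulated intragenic miRNAs whose hosts are
dysregulated with probability 12/71, families of duplicated precursors in
distinct hosts, co-hosted cluster pairs, nested gene pairs, and one planted
term holding half of the dysregulated host set over a 5000-gene universe.

Constructions chosen for exactness of the planted truth:

- Independently placed precursors keep ≥15 kb apart so no unplanned cluster
  can arise at the default 10 kb chaining gap; cluster pairs are placed at a
  2 kb gap inside one intron.
- Nested gene pairs put a small coding gene inside a long intron of an
  outer gene and the planted miRNA inside the inner gene's intron, so the
  smallest-span resolution rule is exercised with a known answer; the
  containing outer intron is reserved against other placements.
- Dysregulated intragenic matures are chosen with pairwise-distinct host
  genes, and background dysregulated genes exclude all their hosts, so the
  measured co-dysregulation count is an exact Bernoulli(12/71) sample per
  miRNA — its mean over seeds is the 16.9% benchmark.
- DE tables place adjusted p strictly below 0.09 / above 0.12, so the 0.1
  selection boundary is never ambiguous.

What the generator does **not** emulate: read-level counts and dispersion
(DE statistics are drawn directly), overlapping gene loci beyond the
deliberate nested pairs, multi-isoform genes (isoform disagreement is
covered by hand-written cases instead), chained clusters longer than two,
and any sequence realism beyond exact identity within families.  Passing
closed-loop tests therefore demonstrates correctness of the geometry,
set logic and statistics — not robustness to annotation noise in real
genomes.

The packaged demonstration bundle encodes the mir-103a-1→PANK3,
mir-103a-2→PANK2, mir-107→PANK1 (intronic) and mir-1307→USMG5 (exonic)
relationships with a shared, single-substitution-separated miR-103a-3p /
miR-107 sequence pair.  Its coordinates are invented placeholders: only
containment, strand and sequence identity are meaningful.

## Statistical calibration checks

The enrichment engine's null behaviour is checked by drawing random queries
from the universe and measuring the frequency of p < 0.05 across terms.
Because the hypergeometric is discrete, the attainable rejection level is
strictly below the nominal one; the calibration study therefore uses large
disjoint terms (universe 20 000, ten disjoint terms of 2 000, query 2 000),
where the attainable level (~0.047) sits inside the two-sided binomial 99%
band around 0.05 for the 5 000 pooled tests.  With small terms the same
check would fail for any correct implementation, for discreteness alone.

Problem sizes used by the test suite and the acceptance script (300-gene /
150-miRNA default simulations; 30-gene / 12-miRNA bundles for the
oracle-equivalence sweeps; 50–500 replicates per statistical check) were
chosen so each property is measured with useful power while the whole suite
stays interactive.

## Known limitations

- Host assignment is purely geometric; it does not consult curated host
  databases, and transcript-support levels or biotype subtleties
  (e.g. read-through loci) are not modelled.
- Family collapsing uses exact full-length identity; near-identical
  paralogs that sequencing may still confuse are not grouped.
- The co-dysregulation overlap p treats the dysregulated-gene list as a
  simple random draw from the universe, ignoring expression-dependent
  detection bias.
- Only over-representation is tested; no ranked (GSEA-style) statistics,
  and no network or upstream-regulator reconstruction.
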