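"""Seeded synthetic input bundles with planted ground truth.

The generator lays out non-overlapping multi-exon genes on one chromosome
(plus a configurable number of deliberately nested gene pairs), embeds
miRNA precursors in introns, exons, antisense orientations and intergenic
space according to the configured fractions, plants sequence-identical
mature pairs across distinct hosts (families), co-hosted precursor pairs
(clusters), a dysregulated miRNA set with a controlled host
co-dysregulation rate, and a gene-set collection containing one term
enriched for the dysregulated hosts.  Every output is emitted in the same
plain-text formats the analysis pipeline consumes, alongside a
``truth.json`` with the planted answers, so the whole pipeline is testable
end to end without any external download.

Default parameter values mirror the application that motivated the package:
71 dysregulated intragenic miRNAs of which a fraction 12/71 sit inside a
dysregulated host gene.

``demo_fixture`` builds the small hand-written demonstration bundle encoding the
miR-103a/107 -> PANK1/2/3 and miR-1307 -> USMG5 host relationships.  Its
coordinates are synthetic placeholders: only the containment, strand and
sequence-identity relations are meaningful.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import annotation_io as aio
from .errors import InvalidConfigError
from .model import (
    DysregulationRecord,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    MatureMirna,
    MirnaAnnotation,
    Transcript,
)

CHROM = "chr1"
_RNA = np.array(list("ACGU"))

#: minimum distance between independently placed precursors, so that no
#: unplanned cluster can arise at the default clustering gap
MIN_MIRNA_SEPARATION = 15_000


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the motivating cohort."""

    seed: int = 0
    n_genes: int = 300
    n_noncoding_genes: int = 15  # of n_genes; lincRNA decoys, never hosts
    n_mirnas: int = 150
    fraction_intronic: float = 0.45
    fraction_exonic: float = 0.15
    fraction_antisense: float = 0.15
    fraction_intergenic: float = 0.25
    n_families: int = 3  # duplicated-sequence precursor pairs, distinct hosts
    n_clusters: int = 3  # co-hosted precursor pairs within one intron
    n_nested_gene_pairs: int = 2
    cluster_gap: int = 2000
    n_dysregulated_mirnas: int = 100
    n_intragenic_dysregulated: int = 71
    codysregulation_rate: float = 12 / 71
    n_background_dysregulated_genes: int = 30
    planted_term_size: int = 100
    planted_term_host_fraction: float = 0.5
    n_random_terms: int = 50
    random_term_size_min: int = 20
    random_term_size_max: int = 200
    universe_size: int = 5000
    targets_per_mirna: int = 20

    def validate(self) -> None:
        fr = (
            self.fraction_intronic
            + self.fraction_exonic
            + self.fraction_antisense
            + self.fraction_intergenic
        )
        if not math.isclose(fr, 1.0, abs_tol=1e-9):
            raise InvalidConfigError(f"context fractions sum to {fr}, not 1")
        if not (0.0 <= self.codysregulation_rate <= 1.0):
            raise InvalidConfigError("codysregulation_rate must lie in [0, 1]")
        for name in (
            "n_genes",
            "n_noncoding_genes",
            "n_mirnas",
            "n_families",
            "n_clusters",
            "n_nested_gene_pairs",
            "n_dysregulated_mirnas",
            "n_intragenic_dysregulated",
            "n_background_dysregulated_genes",
            "planted_term_size",
            "n_random_terms",
            "universe_size",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        n_int, n_exo, n_anti, n_inter = self._context_counts()
        if self.n_nested_gene_pairs + 2 * self.n_clusters > n_int:
            raise InvalidConfigError(
                "more nested/cluster placements than intronic miRNA slots"
            )
        if 2 * self.n_families > n_int - 2 * self.n_clusters - self.n_nested_gene_pairs:
            raise InvalidConfigError("not enough plain intronic miRNAs for families")
        if self.n_intragenic_dysregulated > n_int + n_exo:
            raise InvalidConfigError(
                "n_intragenic_dysregulated exceeds the intragenic miRNA count"
            )
        if self.n_dysregulated_mirnas < self.n_intragenic_dysregulated:
            raise InvalidConfigError(
                "n_dysregulated_mirnas smaller than its intragenic component"
            )
        if self.n_dysregulated_mirnas - self.n_intragenic_dysregulated > 2 * (
            n_anti + n_inter
        ):
            raise InvalidConfigError("not enough non-intragenic matures to dysregulate")
        if self.universe_size < self.n_genes + self.n_nested_gene_pairs:
            raise InvalidConfigError("universe_size smaller than the gene count")
        if self.planted_term_size > self.universe_size:
            raise InvalidConfigError("planted term larger than the universe")
        n_from_hosts = round(self.planted_term_size * self.planted_term_host_fraction)
        if n_from_hosts > self.n_intragenic_dysregulated:
            raise InvalidConfigError(
                "planted term draws more host genes than will be dysregulated"
            )

    def _context_counts(self) -> Tuple[int, int, int, int]:
        n_int = round(self.fraction_intronic * self.n_mirnas)
        n_exo = round(self.fraction_exonic * self.n_mirnas)
        n_anti = round(self.fraction_antisense * self.n_mirnas)
        n_inter = self.n_mirnas - n_int - n_exo - n_anti
        if n_inter < 0:
            raise InvalidConfigError("rounded context counts exceed n_mirnas")
        return n_int, n_exo, n_anti, n_inter


@dataclass
class GroundTruth:
    """Planted answers for one generated bundle."""

    contexts: Dict[str, str] = field(default_factory=dict)  # precursor -> context
    sublocations: Dict[str, str] = field(default_factory=dict)
    hosts: Dict[str, Optional[str]] = field(default_factory=dict)
    families: Dict[str, List[str]] = field(default_factory=dict)  # mature -> precursors
    clusters: List[List[str]] = field(default_factory=list)
    dysregulated_matures: Dict[str, str] = field(default_factory=dict)
    intragenic_dysregulated: List[str] = field(default_factory=list)
    codysregulated: List[str] = field(default_factory=list)
    dysregulated_genes: List[str] = field(default_factory=list)
    host_gene_set: List[str] = field(default_factory=list)
    planted_term_id: str = "PLANTED"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


@dataclass
class Bundle:
    """In-memory objects plus rendered text files for one simulated study."""

    config: Optional[SimulationConfig]
    genes: List[GeneModel]
    mirnas: List[MirnaAnnotation]
    sequences: Dict[str, str]
    mirna_de: List[DysregulationRecord]
    gene_de: List[DysregulationRecord]
    collection: GeneSetCollection
    target_map: Dict[str, Set[str]]
    universe: List[str]
    truth: Optional[GroundTruth]
    files: Dict[str, str]

    def write(self, outdir: os.PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in sorted(self.files.items()):
            (out / name).write_text(text)


def _render_files(bundle: Bundle) -> None:
    bundle.files = {
        "genes.gff3": aio.gene_models_to_gff3(bundle.genes),
        "mirnas.gff3": aio.mirnas_to_gff3(bundle.mirnas),
        "sequences.tsv": aio.sequences_to_tsv(bundle.sequences),
        "mirna_de.tsv": aio.de_records_to_tsv(bundle.mirna_de),
        "gene_de.tsv": aio.de_records_to_tsv(bundle.gene_de),
        "genesets.gmt": aio.collection_to_gmt(bundle.collection),
        "target_map.tsv": aio.target_map_to_tsv(bundle.target_map),
        "universe.txt": "\n".join(bundle.universe) + "\n",
    }
    if bundle.truth is not None:
        bundle.files["truth.json"] = bundle.truth.to_json()


# ---------------------------------------------------------------------------
# random generator
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, used: Set[str]) -> str:
    while True:
        seq = "".join(rng.choice(_RNA, size=22))
        if seq not in used:
            used.add(seq)
            return seq


def _build_gene(
    rng: np.random.Generator, gene_id: str, symbol: str, biotype: str,
    start: int, strand: str,
) -> GeneModel:
    n_ex = int(rng.integers(2, 6))
    pos = start
    exons: List[GenomicInterval] = []
    for j in range(n_ex):
        elen = int(rng.integers(150, 401))
        exons.append(GenomicInterval(CHROM, pos, pos + elen, strand))
        pos += elen
        if j < n_ex - 1:
            pos += int(rng.integers(1500, 4001))
    span = GenomicInterval(CHROM, start, pos, strand)
    return GeneModel(
        gene_id, symbol, biotype, span,
        (Transcript(f"{gene_id}.t1", tuple(exons)),),
    )


def generate(config: SimulationConfig) -> Bundle:
    """Generate one deterministic bundle for the given configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_int, n_exo, n_anti, n_inter = config._context_counts()

    # --- gene layout -------------------------------------------------------
    noncoding_idx = set(
        rng.choice(config.n_genes, size=config.n_noncoding_genes, replace=False)
    )
    genes: List[GeneModel] = []
    cursor = 10_000
    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lincRNA" if i in noncoding_idx else "protein_coding"
        gene = _build_gene(rng, f"G{i:04d}", f"GENE{i}", biotype, cursor, strand)
        genes.append(gene)
        cursor = gene.span.end + int(rng.integers(8000, 20001))

    coding = [g for g in genes if g.is_protein_coding]

    # nested pairs: a small protein-coding gene placed inside a long intron
    # of an outer gene; the containing intron is then reserved so no other
    # placement accidentally lands in both
    reserved_introns: Set[Tuple[str, int]] = set()
    inner_genes: List[GeneModel] = []
    outer_pool = [
        (g, i, intr)
        for g in coding
        for i, intr in enumerate(g.transcripts[0].introns())
        if intr.length >= 3600
    ]
    rng.shuffle(outer_pool)
    if len(outer_pool) < config.n_nested_gene_pairs:
        raise InvalidConfigError("not enough long introns for nested gene pairs")
    used_outer: Set[str] = set()
    k = 0
    for outer, i_intron, intron in outer_pool:
        if k >= config.n_nested_gene_pairs:
            break
        if outer.gene_id in used_outer:
            continue
        gid = f"G{config.n_genes + k:04d}"
        inner = GeneModel(
            gid,
            f"NESTED{k}",
            "protein_coding",
            GenomicInterval(CHROM, intron.start + 200, intron.start + 200 + 1500, outer.span.strand),
            (
                Transcript(
                    f"{gid}.t1",
                    (
                        GenomicInterval(CHROM, intron.start + 200, intron.start + 400, outer.span.strand),
                        GenomicInterval(CHROM, intron.start + 1500, intron.start + 1700, outer.span.strand),
                    ),
                ),
            ),
        )
        inner_genes.append(inner)
        reserved_introns.add((outer.gene_id, i_intron))
        used_outer.add(outer.gene_id)
        k += 1
    genes = sorted(genes + inner_genes, key=lambda g: (g.span.start, g.gene_id))

    # --- miRNA placement ---------------------------------------------------
    truth = GroundTruth()
    placed: List[Tuple[int, int]] = []  # precursor spans, for separation
    mirna_specs: List[dict] = []  # precursor placements before object build

    def too_close(start: int, end: int, ignore: Optional[Tuple[int, int]] = None) -> bool:
        for (s, e) in placed:
            if ignore is not None and (s, e) == ignore:
                continue
            if start - e < MIN_MIRNA_SEPARATION and s - end < MIN_MIRNA_SEPARATION:
                return True
        return False

    def place_in(interval: GenomicInterval, margin: int = 50) -> Optional[Tuple[int, int]]:
        plen = int(rng.integers(80, 101))
        lo, hi = interval.start + margin, interval.end - margin - plen
        if hi < lo:
            return None
        for _ in range(10):
            s = int(rng.integers(lo, hi + 1))
            if not too_close(s, s + plen):
                placed.append((s, s + plen))
                return (s, s + plen)
        return None

    used_host_genes: Set[str] = set()

    def record(span: Tuple[int, int], strand: str, context: str, subloc: str,
               host: Optional[str]) -> int:
        idx = len(mirna_specs)
        mirna_specs.append(
            {"span": span, "strand": strand, "context": context,
             "subloc": subloc, "host": host}
        )
        return idx

    # nested placements: inside the inner gene's intron -> two containers,
    # smallest span (the inner gene) must win
    for inner in inner_genes:
        intron = inner.transcripts[0].introns()[0]
        span = place_in(intron, margin=50)
        if span is None:
            raise InvalidConfigError("could not place nested miRNA")
        record(span, inner.span.strand, "intragenic_sense", "intronic", inner.gene_id)
        used_host_genes.add(inner.gene_id)

    # cluster placements: two precursors in one long intron, gap = cluster_gap
    intron_pool = [
        (g, i, intr)
        for g in coding
        for i, intr in enumerate(g.transcripts[0].introns())
        if (g.gene_id, i) not in reserved_introns and g.gene_id not in used_host_genes
    ]
    rng.shuffle(intron_pool)
    cluster_pool = [
        t for t in intron_pool
        if t[2].length >= 300 + config.cluster_gap + 300
    ]
    n_placed_clusters = 0
    for g, i_intron, intron in cluster_pool:
        if n_placed_clusters >= config.n_clusters:
            break
        first = place_in(
            GenomicInterval(CHROM, intron.start, intron.start + 250, g.span.strand),
            margin=20,
        )
        if first is None:
            continue
        second_start = first[1] + config.cluster_gap
        plen2 = int(rng.integers(80, 101))
        if second_start + plen2 + 50 > intron.end:
            continue
        placed.append((second_start, second_start + plen2))
        a = record(first, g.span.strand, "intragenic_sense", "intronic", g.gene_id)
        b = record((second_start, second_start + plen2), g.span.strand,
                   "intragenic_sense", "intronic", g.gene_id)
        truth.clusters.append([a, b])  # indices for now; names later
        used_host_genes.add(g.gene_id)
        reserved_introns.add((g.gene_id, i_intron))
        n_placed_clusters += 1
    if n_placed_clusters < config.n_clusters:
        raise InvalidConfigError("could not place all requested clusters")

    def fill_quota(quota: int, kind: str) -> None:
        if quota <= 0:
            return
        n_done = 0
        if kind in ("intronic", "antisense"):
            pool = [
                (g, i, intr)
                for g in coding + (inner_genes if kind == "intronic" else [])
                for i, intr in enumerate(g.transcripts[0].introns())
                if (g.gene_id, i) not in reserved_introns
                and g.gene_id not in used_host_genes
                and intr.length >= 300
            ]
        elif kind == "exonic":
            pool = [
                (g, i, e)
                for g in coding
                for i, e in enumerate(g.transcripts[0].exons)
                if g.gene_id not in used_host_genes and e.length >= 150
            ]
        else:  # intergenic: gaps between merged gene-span coverage
            merged: List[List[int]] = []
            for s in sorted(g.span for g in genes):
                if merged and s.start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], s.end)
                else:
                    merged.append([s.start, s.end])
            pool = []
            for a, b in zip(merged, merged[1:]):
                if b[0] - a[1] >= 4000:
                    pool.append(
                        (None, 0, GenomicInterval(CHROM, a[1] + 1000, b[0] - 1000, "+"))
                    )
        rng.shuffle(pool)
        seen_genes: Set[str] = set()
        for g, _i, interval in pool:
            if n_done >= quota:
                break
            if g is not None and (g.gene_id in seen_genes or g.gene_id in used_host_genes):
                continue
            if kind == "intronic":
                strand = g.span.strand
            elif kind == "antisense":
                strand = "-" if g.span.strand == "+" else "+"
            elif kind == "exonic":
                strand = g.span.strand
                if interval.length < 80 + 2 * 10 + 5:
                    continue
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            margin = 10 if kind == "exonic" else 50
            span = place_in(interval, margin=margin)
            if span is None:
                continue
            if kind == "intronic":
                record(span, strand, "intragenic_sense", "intronic", g.gene_id)
                used_host_genes.add(g.gene_id)
            elif kind == "exonic":
                record(span, strand, "intragenic_sense", "exonic", g.gene_id)
                used_host_genes.add(g.gene_id)
            elif kind == "antisense":
                record(span, strand, "intragenic_antisense", "intronic", None)
                seen_genes.add(g.gene_id)
            else:
                record(span, strand, "intergenic", "none", None)
            n_done += 1
        if n_done < quota:
            raise InvalidConfigError(
                f"could not place {quota} {kind} miRNA(s); only {n_done} fitted"
            )

    fill_quota(n_int - len(inner_genes) - 2 * n_placed_clusters, "intronic")
    fill_quota(n_exo, "exonic")
    fill_quota(n_anti, "antisense")
    fill_quota(n_inter, "intergenic")

    # --- mature products, names, sequences, families -----------------------
    order = sorted(range(len(mirna_specs)), key=lambda i: mirna_specs[i]["span"][0])
    rank_of = {idx: r for r, idx in enumerate(order)}
    used_seqs: Set[str] = set()
    mature_entries: Dict[int, List[MatureMirna]] = {}
    for idx, spec in enumerate(mirna_specs):
        r = rank_of[idx]
        s, e = spec["span"]
        strand = spec["strand"]
        spec["precursor_id"] = f"mir-{r:03d}"
        m5 = MatureMirna(
            f"miR-{r:03d}-5p", f"miR-{r:03d}-5p",
            GenomicInterval(CHROM, s + 8, s + 30, strand),
        )
        m3 = MatureMirna(
            f"miR-{r:03d}-3p", f"miR-{r:03d}-3p",
            GenomicInterval(CHROM, e - 30, e - 8, strand),
        )
        mature_entries[idx] = [m5, m3]

    # family pairs: overwrite the 3p mature of two distinct-host intronic
    # precursors with one shared id and one shared sequence
    plain_intronic = [
        idx for idx, spec in enumerate(mirna_specs)
        if spec["context"] == "intragenic_sense"
        and spec["subloc"] == "intronic"
        and not any(idx in c for c in truth.clusters)
        and mirna_specs[idx]["host"] is not None
    ]
    fam_candidates = list(plain_intronic)
    rng.shuffle(fam_candidates)
    fam_pairs: List[Tuple[int, int]] = []
    taken: Set[int] = set()
    for i in fam_candidates:
        if len(fam_pairs) >= config.n_families:
            break
        if i in taken:
            continue
        mate = next(
            (
                j
                for j in fam_candidates
                if j not in taken
                and j != i
                and mirna_specs[j]["host"] != mirna_specs[i]["host"]
            ),
            None,
        )
        if mate is None:
            break
        taken.update((i, mate))
        fam_pairs.append((i, mate))
    if len(fam_pairs) < config.n_families:
        raise InvalidConfigError("could not form the requested family pairs")
    fam_sequences: Dict[str, str] = {}
    for j, (a, b) in enumerate(fam_pairs):
        shared_id = f"miR-fam{j}-3p"
        seq = _random_sequence(rng, used_seqs)
        for idx in (a, b):
            old = mature_entries[idx][1]
            mature_entries[idx][1] = MatureMirna(shared_id, shared_id, old.span)
        fam_sequences[shared_id] = seq
        truth.families[shared_id] = sorted(
            mirna_specs[idx]["precursor_id"] for idx in (a, b)
        )

    sequences: Dict[str, str] = dict(fam_sequences)
    mirnas: List[MirnaAnnotation] = []
    for idx in order:
        spec = mirna_specs[idx]
        s, e = spec["span"]
        pid = spec["precursor_id"]
        for m in mature_entries[idx]:
            sequences.setdefault(m.mature_id, _random_sequence(rng, used_seqs))
        mirnas.append(
            MirnaAnnotation(
                pid, pid,
                GenomicInterval(CHROM, s, e, spec["strand"]),
                tuple(mature_entries[idx]),
            )
        )
        truth.contexts[pid] = spec["context"]
        truth.sublocations[pid] = spec["subloc"]
        truth.hosts[pid] = spec["host"]
    truth.clusters = sorted(
        sorted(mirna_specs[i]["precursor_id"] for i in pair) for pair in truth.clusters
    )

    # --- dysregulation -----------------------------------------------------
    # intragenic candidates: the 3p mature of each intragenic precursor;
    # family-shared matures appear once with the union of their hosts.
    # Selected matures are constrained to pairwise-distinct host genes so
    # the co-dysregulation count is an exact Bernoulli sample per miRNA.
    host_sets: Dict[str, Set[str]] = {}
    for idx, spec in enumerate(mirna_specs):
        if spec["context"] != "intragenic_sense":
            continue
        mid = mature_entries[idx][1].mature_id
        host_sets.setdefault(mid, set()).add(spec["host"])

    candidates = sorted(host_sets)
    rng.shuffle(candidates)
    selected_intragenic: List[str] = []
    used_hosts: Set[str] = set()
    for mid in candidates:
        if len(selected_intragenic) >= config.n_intragenic_dysregulated:
            break
        if host_sets[mid] & used_hosts:
            continue
        selected_intragenic.append(mid)
        used_hosts |= host_sets[mid]
    if len(selected_intragenic) < config.n_intragenic_dysregulated:
        raise InvalidConfigError(
            "cannot select the requested number of intragenic dysregulated "
            "miRNAs with distinct hosts"
        )

    other_matures = sorted(
        {
            m.mature_id
            for idx, spec in enumerate(mirna_specs)
            if spec["context"] != "intragenic_sense"
            for m in mature_entries[idx]
        }
    )
    rng.shuffle(other_matures)
    n_other = config.n_dysregulated_mirnas - config.n_intragenic_dysregulated
    selected_other = other_matures[:n_other]

    for mid in selected_intragenic + selected_other:
        truth.dysregulated_matures[mid] = "up" if rng.random() < 0.5 else "down"
    truth.intragenic_dysregulated = sorted(selected_intragenic)
    truth.host_gene_set = sorted(
        set().union(*(host_sets[mid] for mid in selected_intragenic))
        if selected_intragenic
        else set()
    )

    # co-dysregulation: Bernoulli per selected intragenic miRNA; the chosen
    # host goes onto the dysregulated-gene list
    codys_hosts: Set[str] = set()
    for mid in sorted(selected_intragenic):
        if rng.random() < config.codysregulation_rate:
            truth.codysregulated.append(mid)
            hosts = sorted(host_sets[mid])
            codys_hosts.add(hosts[int(rng.integers(0, len(hosts)))])
    truth.codysregulated.sort()

    all_gene_ids = [g.gene_id for g in genes]
    protected = set().union(*(host_sets[m] for m in selected_intragenic)) \
        if selected_intragenic else set()
    background_pool = sorted(set(all_gene_ids) - protected)
    rng.shuffle(background_pool)
    background = background_pool[: config.n_background_dysregulated_genes]
    truth.dysregulated_genes = sorted(codys_hosts | set(background))

    # --- DE tables ---------------------------------------------------------
    def de_records(ids: Sequence[str], dys: Dict[str, str]) -> List[DysregulationRecord]:
        recs = []
        for fid in ids:
            if fid in dys:
                padj = float(rng.uniform(0.001, 0.09))
                lfc = float(rng.uniform(1.0, 4.0))
                if dys[fid] == "down":
                    lfc = -lfc
            else:
                padj = float(rng.uniform(0.12, 0.95))
                lfc = float(rng.normal(0.0, 0.2))
            pval = padj * float(rng.uniform(0.05, 0.8))
            recs.append(DysregulationRecord(fid, round(lfc, 4), round(pval, 6), round(padj, 6)))
        return recs

    all_mature_ids = sorted({m.mature_id for mir in mirnas for m in mir.matures})
    mirna_de = de_records(all_mature_ids, truth.dysregulated_matures)
    gene_dirs = {g: ("up" if rng.random() < 0.5 else "down") for g in truth.dysregulated_genes}
    gene_de = de_records(sorted(all_gene_ids), gene_dirs)

    # --- universe, gene sets, targets --------------------------------------
    filler = [f"U{i:05d}" for i in range(config.universe_size - len(all_gene_ids))]
    universe = sorted(all_gene_ids) + filler

    n_from_hosts = round(config.planted_term_size * config.planted_term_host_fraction)
    hosts_sorted = list(truth.host_gene_set)
    rng.shuffle(hosts_sorted)
    non_hosts = sorted(set(universe) - set(truth.host_gene_set))
    rng.shuffle(non_hosts)
    planted_members = set(hosts_sorted[:n_from_hosts]) | set(
        non_hosts[: config.planted_term_size - n_from_hosts]
    )
    sets = {
        "PLANTED": GeneSet("PLANTED", "planted enriched term", frozenset(planted_members))
    }
    uni_arr = np.array(universe)
    for j in range(config.n_random_terms):
        size = int(rng.integers(config.random_term_size_min, config.random_term_size_max + 1))
        members = frozenset(rng.choice(uni_arr, size=size, replace=False).tolist())
        sets[f"T{j:03d}"] = GeneSet(f"T{j:03d}", "random synthetic term", members)
    collection = GeneSetCollection(sets)

    target_map = {
        mid: set(rng.choice(uni_arr, size=config.targets_per_mirna, replace=False).tolist())
        for mid in all_mature_ids
    }

    bundle = Bundle(
        config=config,
        genes=genes,
        mirnas=mirnas,
        sequences=sequences,
        mirna_de=mirna_de,
        gene_de=gene_de,
        collection=collection,
        target_map=target_map,
        universe=universe,
        truth=truth,
        files={},
    )
    _render_files(bundle)
    return bundle


# ---------------------------------------------------------------------------
# the packaged demonstration bundle
# ---------------------------------------------------------------------------

# mature sequences: the shared miR-103a-3p sequence differs from miR-107 by a
# single nucleotide, which is exactly why the family rule matters
_FIXTURE_SEQS = {
    "miR-103a-3p": "AGCAGCAUUGUACAGGGCUAUGA",
    "miR-107": "AGCAGCAUUGUACAGGGCUAUCA",
    "miR-103a-1-5p": "GGCUUCUUUACAGUGCUGCCUUG",
    "miR-103a-2-5p": "AGCUUCUUUACAGUGCUGCCUUG",
    "miR-1307-5p": "UCGACCGGACCUCGACCGGCUCG",
    "miR-1307-3p": "ACUCGGCGUGGCGUCGGUCGUGA",
    "miR-syn1-5p": "UAGGUAGUUUCAUGUUGUUGGGA",
}


def _fixture_gene(gene_id: str, chrom: str, strand: str,
                  exon_spec: Sequence[Tuple[int, int]]) -> GeneModel:
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spec)
    span = GenomicInterval(chrom, exon_spec[0][0], exon_spec[-1][1], strand)
    return GeneModel(gene_id, gene_id, "protein_coding", span,
                     (Transcript(f"{gene_id}.t1", exons),))


def _fixture_mirna(pid: str, chrom: str, start: int, strand: str,
                   matures: Sequence[Tuple[str, int]]) -> MirnaAnnotation:
    span = GenomicInterval(chrom, start, start + 85, strand)
    mats = tuple(
        MatureMirna(mid, mid, GenomicInterval(chrom, start + off, start + off + 22, strand))
        for mid, off in matures
    )
    return MirnaAnnotation(pid, pid, span, mats)


def demo_fixture() -> Bundle:
    """The hand-written bundle encoding the PANK/USMG5 host relationships.

    mir-103a-1 sits in an intron of PANK3, mir-103a-2 in an intron of PANK2,
    mir-107 in an intron of PANK1 and mir-1307 in an exon of USMG5; the 3p
    products of the two mir-103a precursors share one mature id and one
    sequence.  The miRNA DE table marks miR-103a-3p and miR-107 upregulated
    and both miR-1307 arms downregulated; the gene DE table marks USMG5
    downregulated.  All coordinates are synthetic placeholders that preserve
    only the containment/strand/sequence relations.
    """
    genes = [
        _fixture_gene("PANK3", "chr5", "-",
                      [(40000, 40400), (44000, 44350), (48000, 48500), (52000, 52600)]),
        _fixture_gene("PANK2", "chr20", "+",
                      [(30000, 30380), (34500, 34900), (39000, 39420), (43000, 43700)]),
        _fixture_gene("PANK1", "chr10", "-",
                      [(60000, 60450), (66000, 66380), (72000, 72500), (78000, 78800)]),
        _fixture_gene("USMG5", "chr10", "+",
                      [(200000, 200250), (202000, 202180), (204000, 205200)]),
        _fixture_gene("SYNG1", "chr2", "+",
                      [(10000, 10300), (14000, 14400), (18000, 18600)]),
    ]
    mirnas = [
        # intron between PANK3 exons 2 and 3 is [44350, 48000)
        _fixture_mirna("mir-103a-1", "chr5", 45600, "-",
                       [("miR-103a-1-5p", 10), ("miR-103a-3p", 52)]),
        # intron between PANK2 exons 1 and 2 is [30380, 34500)
        _fixture_mirna("mir-103a-2", "chr20", 32100, "+",
                       [("miR-103a-2-5p", 10), ("miR-103a-3p", 52)]),
        # intron between PANK1 exons 2 and 3 is [66380, 72000)
        _fixture_mirna("mir-107", "chr10", 69200, "-", [("miR-107", 48)]),
        # last USMG5 exon is [204000, 205200)
        _fixture_mirna("mir-1307", "chr10", 204400, "+",
                       [("miR-1307-5p", 8), ("miR-1307-3p", 50)]),
        # intergenic decoy on chr2, far from SYNG1
        _fixture_mirna("mir-syn1", "chr2", 60000, "+", [("miR-syn1-5p", 12)]),
    ]
    mirna_de = [
        DysregulationRecord("miR-103a-3p", 1.6, 0.0004, 0.004),
        DysregulationRecord("miR-107", 1.2, 0.001, 0.01),
        DysregulationRecord("miR-1307-5p", -1.1, 0.002, 0.02),
        DysregulationRecord("miR-1307-3p", -0.9, 0.003, 0.03),
        DysregulationRecord("miR-syn1-5p", 2.0, 0.004, 0.04),
        DysregulationRecord("miR-103a-1-5p", 0.2, 0.5, 0.8),
        DysregulationRecord("miR-103a-2-5p", -0.1, 0.6, 0.9),
    ]
    gene_de = [
        DysregulationRecord("USMG5", -1.3, 0.001, 0.02),
        DysregulationRecord("PANK1", 0.1, 0.5, 0.7),
        DysregulationRecord("PANK2", 0.2, 0.4, 0.65),
        DysregulationRecord("PANK3", -0.1, 0.6, 0.8),
        DysregulationRecord("SYNG1", 0.0, 0.9, 0.95),
    ]
    sets = {
        "COA_BIOSYNTHESIS": GeneSet(
            "COA_BIOSYNTHESIS", "pantothenate to CoA conversion",
            frozenset({"PANK1", "PANK2", "PANK3", "PPCS", "PPCDC", "COASY"}),
        ),
        "ATP_SYNTHESIS_COUPLING": GeneSet(
            "ATP_SYNTHESIS_COUPLING", "mitochondrial ATP synthase and assembly",
            frozenset({"USMG5", "ATP5F1A", "ATP5F1B", "ATP5MC1", "ATP5PD"}),
        ),
        "CHOLESTEROL_BIOSYNTHESIS": GeneSet(
            "CHOLESTEROL_BIOSYNTHESIS", "sterol synthesis and its regulators",
            frozenset({"HMGCR", "SREBF1", "SREBF2", "LDLR", "MVK"}),
        ),
        "MUSCLE_CONTRACTION": GeneSet(
            "MUSCLE_CONTRACTION", "sarcomere and muscle structural genes",
            frozenset({"DMD", "MYOD1", "ACTA1", "TNNT1", "DES", "SYNG1"}),
        ),
    }
    collection = GeneSetCollection(sets)
    universe = sorted(collection.covered_genes() | {g.gene_id for g in genes})
    target_map = {
        "miR-103a-3p": {"HMGCR", "LDLR", "DES", "PPCS"},
        "miR-107": {"SREBF1", "MVK", "ACTA1"},
        "miR-1307-5p": {"ATP5F1A", "TNNT1"},
        "miR-1307-3p": {"ATP5MC1", "MYOD1"},
        "miR-syn1-5p": {"DMD", "COASY"},
    }
    truth = GroundTruth(
        contexts={
            "mir-103a-1": "intragenic_sense",
            "mir-103a-2": "intragenic_sense",
            "mir-107": "intragenic_sense",
            "mir-1307": "intragenic_sense",
            "mir-syn1": "intergenic",
        },
        sublocations={
            "mir-103a-1": "intronic",
            "mir-103a-2": "intronic",
            "mir-107": "intronic",
            "mir-1307": "exonic",
            "mir-syn1": "none",
        },
        hosts={
            "mir-103a-1": "PANK3",
            "mir-103a-2": "PANK2",
            "mir-107": "PANK1",
            "mir-1307": "USMG5",
            "mir-syn1": None,
        },
        families={"miR-103a-3p": ["mir-103a-1", "mir-103a-2"]},
        clusters=[],
        dysregulated_matures={
            "miR-103a-3p": "up",
            "miR-107": "up",
            "miR-1307-5p": "down",
            "miR-1307-3p": "down",
            "miR-syn1-5p": "up",
        },
        intragenic_dysregulated=["miR-103a-3p", "miR-107", "miR-1307-3p", "miR-1307-5p"],
        codysregulated=["miR-1307-3p", "miR-1307-5p"],
        dysregulated_genes=["USMG5"],
        host_gene_set=["PANK1", "PANK2", "PANK3", "USMG5"],
        planted_term_id="",
    )
    bundle = Bundle(
        config=None,
        genes=sorted(genes, key=lambda g: (g.span.chrom, g.span.start)),
        mirnas=mirnas,
        sequences=dict(_FIXTURE_SEQS),
        mirna_de=mirna_de,
        gene_de=gene_de,
        collection=collection,
        target_map=target_map,
        universe=universe,
        truth=truth,
        files={},
    )
    _render_files(bundle)
    return bundle
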