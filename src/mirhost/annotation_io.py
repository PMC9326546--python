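"""Readers and writers for the standard input formats.

GFF3 gene models and miRBase-dialect miRNA annotations are parsed through
:mod:`gffutils` (in-memory database); a light syntactic pre-pass provides
line-numbered error messages.  Tabular formats (DE tables, sequence tables,
target maps) go through :mod:`pandas`.  All coordinates are converted to the
internal 0-based half-open convention at this boundary and converted back on
write, so the rest of the package never sees GFF3 coordinates.
"""

from __future__ import annotations

import io
import logging
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, TextIO, Union

import gffutils
import pandas as pd

from .errors import Gff3ParseError, GmtFormatError, TableFormatError
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

logger = logging.getLogger(__name__)

Source = Union[str, os.PathLike, TextIO]

#: attribute keys probed, in order, for the gene biotype (Ensembl vs GENCODE)
BIOTYPE_KEYS = ("biotype", "gene_biotype")

_PSEUDO_TRANSCRIPT_SUFFIX = ".pseudo"


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    with open(source, "rt") as fh:
        return fh.read()


def _validate_gff3_syntax(text: str) -> None:
    """Reject malformed GFF3 lines with an error naming the line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise Gff3ParseError(
                f"malformed GFF3 at line {lineno}: expected 9 tab-separated "
                f"fields, found {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise Gff3ParseError(
                f"malformed GFF3 at line {lineno}: non-integer coordinates"
            ) from None
        if start < 1 or end < start:
            raise Gff3ParseError(
                f"malformed GFF3 at line {lineno}: invalid coordinate range "
                f"{start}..{end}"
            )
        if fields[6] not in ("+", "-", ".", "?"):
            raise Gff3ParseError(
                f"malformed GFF3 at line {lineno}: invalid strand {fields[6]!r}"
            )


def _gff_db(text: str) -> gffutils.FeatureDB:
    return gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )


def _interval(feature) -> GenomicInterval:
    # GFF3 1-based inclusive -> 0-based half-open
    return GenomicInterval(
        feature.seqid, feature.start - 1, feature.end, feature.strand
    )


def _attr_first(feature, *keys: str) -> Optional[str]:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def parse_gene_models(source: Source, biotype_keys: Sequence[str] = BIOTYPE_KEYS) -> List[GeneModel]:
    """Parse gene/transcript/exon features from a GFF3 stream.

    Genes lacking any exon feature are kept with a single pseudo-exon equal
    to their span and flagged (``pseudo_exon=True``).  Exons with no
    resolvable gene ancestor are skipped with a logged warning.  The parser
    does not filter on biotype; that happens downstream.
    """
    text = _read_text(source)
    _validate_gff3_syntax(text)
    db = _gff_db(text)

    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        span = _interval(g)
        biotype = _attr_first(g, *biotype_keys) or ""
        symbol = _attr_first(g, "Name", "gene_name") or g.id

        transcripts: List[Transcript] = []
        direct_exons: List[GenomicInterval] = []
        for child in db.children(g, level=1):
            if child.featuretype == "exon":
                direct_exons.append(_interval(child))
                continue
            exons = [
                _interval(e)
                for e in db.children(child, level=1, featuretype="exon")
            ]
            if exons:
                transcripts.append(Transcript(child.id, tuple(exons)))
        if direct_exons:
            # exons parented directly on the gene form one implicit transcript
            transcripts.append(Transcript(f"{g.id}.t0", tuple(direct_exons)))

        pseudo = not transcripts
        if pseudo:
            transcripts = [
                Transcript(
                    f"{g.id}{_PSEUDO_TRANSCRIPT_SUFFIX}",
                    (GenomicInterval(span.chrom, span.start, span.end, span.strand),),
                )
            ]
        try:
            genes.append(
                GeneModel(g.id, symbol, biotype, span, tuple(transcripts), pseudo)
            )
        except ValueError as exc:
            raise Gff3ParseError(f"inconsistent gene {g.id}: {exc}") from exc

    n_orphan = 0
    for e in db.features_of_type("exon"):
        if not any(True for _ in db.parents(e, featuretype="gene")):
            n_orphan += 1
    if n_orphan:
        logger.warning("skipped %d exon(s) with no resolvable gene ancestor", n_orphan)

    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def gene_models_to_gff3(genes: Iterable[GeneModel]) -> str:
    """Render gene models back to GFF3 (inverse of :func:`parse_gene_models`)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
        s = g.span
        attrs = f"ID={g.gene_id};Name={g.symbol}"
        if g.biotype:
            attrs += f";biotype={g.biotype}"
        lines.append(
            f"{s.chrom}\tmirhost\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t{attrs}"
        )
        if g.pseudo_exon:
            continue
        for t in g.transcripts:
            lines.append(
                f"{s.chrom}\tmirhost\tmRNA\t{t.exons[0].start + 1}\t{t.exons[-1].end}"
                f"\t.\t{s.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}"
            )
            for i, e in enumerate(t.exons, start=1):
                lines.append(
                    f"{s.chrom}\tmirhost\texon\t{e.start + 1}\t{e.end}\t.\t{s.strand}"
                    f"\t.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# miRNA annotations (miRBase GFF3 dialect)
# ---------------------------------------------------------------------------


def parse_mirna_annotations(source: Source) -> List[MirnaAnnotation]:
    """Parse ``miRNA_primary_transcript`` + ``miRNA`` features.

    Mature features are linked to their precursor via ``Derives_from``;
    a mature referencing an absent precursor, or lacking the attribute,
    is a referential-integrity error.  Matures within a precursor are
    ordered by genomic start.
    """
    text = _read_text(source)
    _validate_gff3_syntax(text)
    db = _gff_db(text)

    precursors: Dict[str, dict] = {}
    order: List[str] = []
    for p in db.features_of_type("miRNA_primary_transcript"):
        precursors[p.id] = {
            "name": _attr_first(p, "Name") or p.id,
            "span": _interval(p),
            "matures": [],
        }
        order.append(p.id)

    for m in db.features_of_type("miRNA"):
        parent = _attr_first(m, "Derives_from")
        label = _attr_first(m, "Name") or m.id
        if parent is None:
            raise Gff3ParseError(
                f"mature miRNA {label} has no Derives_from attribute"
            )
        if parent not in precursors:
            raise Gff3ParseError(
                f"mature miRNA {label}: Derives_from references absent "
                f"precursor {parent!r}"
            )
        precursors[parent]["matures"].append(
            MatureMirna(mature_id=label, name=label, span=_interval(m))
        )

    out: List[MirnaAnnotation] = []
    for pid in order:
        rec = precursors[pid]
        if not rec["matures"]:
            raise Gff3ParseError(f"precursor {pid} has no mature products")
        try:
            out.append(
                MirnaAnnotation(pid, rec["name"], rec["span"], tuple(rec["matures"]))
            )
        except ValueError as exc:
            raise Gff3ParseError(str(exc)) from exc
    out.sort(key=lambda m: (m.span.chrom, m.span.start, m.precursor_id))
    return out


def mirnas_to_gff3(mirnas: Iterable[MirnaAnnotation]) -> str:
    """Render miRNA annotations in the miRBase GFF3 dialect."""
    lines = ["##gff-version 3"]
    for mir in sorted(mirnas, key=lambda m: (m.span.chrom, m.span.start, m.precursor_id)):
        s = mir.span
        lines.append(
            f"{s.chrom}\t.\tmiRNA_primary_transcript\t{s.start + 1}\t{s.end}\t.\t"
            f"{s.strand}\t.\tID={mir.precursor_id};Name={mir.name}"
        )
        for i, m in enumerate(mir.matures, start=1):
            e = m.span
            lines.append(
                f"{e.chrom}\t.\tmiRNA\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                f"ID={mir.precursor_id}.m{i};Name={m.mature_id};"
                f"Derives_from={mir.precursor_id}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {"id": "id", "log2fc": "log2FC", "pvalue": "pvalue", "padj": "padj"}


def parse_de_table(
    source: Source, column_map: Optional[Mapping[str, str]] = None
) -> List[DysregulationRecord]:
    """Parse a tab-separated differential-expression results table.

    ``column_map`` maps the logical names ``id/log2fc/pvalue/padj`` to the
    table's actual headers (e.g. a DESeq2 export uses ``log2FoldChange``).
    Rows whose padj (or any statistic) does not parse as a finite number are
    dropped, with the count logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(_as_buffer(source), sep="\t", dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"missing column(s) {missing}; available headers: {list(df.columns)}"
        )
    records: List[DysregulationRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        vals = {
            k: pd.to_numeric(row[cmap[k]], errors="coerce")
            for k in ("log2fc", "pvalue", "padj")
        }
        try:
            records.append(
                DysregulationRecord(
                    str(row[cmap["id"]]),
                    float(vals["log2fc"]),
                    float(vals["pvalue"]),
                    float(vals["padj"]),
                )
            )
        except (ValueError, TypeError):
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d DE row(s) with non-numeric statistics", n_dropped)
    return records


def de_records_to_tsv(records: Iterable[DysregulationRecord]) -> str:
    lines = ["id\tlog2FC\tpvalue\tpadj"]
    for r in records:
        lines.append(f"{r.feature_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.padj:.6g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def parse_gmt(source: Source) -> GeneSetCollection:
    """Parse a GMT stream: ``term<TAB>description<TAB>member...`` per line."""
    sets: Dict[str, GeneSet] = {}
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtFormatError(
                f"GMT line {lineno}: expected at least 3 tab-separated fields"
            )
        term, description = fields[0], fields[1]
        if term in sets:
            raise GmtFormatError(f"GMT line {lineno}: duplicate term id {term!r}")
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise GmtFormatError(f"GMT line {lineno}: term {term!r} has no members")
        sets[term] = GeneSet(term, description, members)
    return GeneSetCollection(sets)


def collection_to_gmt(collection: GeneSetCollection) -> str:
    lines = []
    for term in sorted(collection.sets):
        s = collection.sets[term]
        lines.append("\t".join([term, s.description, *sorted(s.members)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence table and target map
# ---------------------------------------------------------------------------


def parse_sequence_table(source: Source) -> Dict[str, str]:
    """Parse ``mature_id<TAB>sequence`` rows (an optional header is skipped)."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise TableFormatError(
                f"sequence table line {lineno}: expected 2 tab-separated fields"
            )
        if lineno == 1 and fields[0].lower() in ("mature_id", "id"):
            continue
        out[fields[0]] = fields[1]
    return out


def sequences_to_tsv(sequences: Mapping[str, str]) -> str:
    lines = ["mature_id\tsequence"]
    for mid in sorted(sequences):
        lines.append(f"{mid}\t{sequences[mid]}")
    return "\n".join(lines) + "\n"


def parse_target_map(source: Source) -> Dict[str, Set[str]]:
    """Parse ``mirna_id<TAB>gene_id`` rows into a miRNA -> target-set map."""
    out: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise TableFormatError(
                f"target map line {lineno}: expected 2 tab-separated fields"
            )
        if lineno == 1 and fields[0].lower() in ("mirna_id", "id"):
            continue
        out.setdefault(fields[0], set()).add(fields[1])
    return out


def target_map_to_tsv(target_map: Mapping[str, Set[str]]) -> str:
    lines = ["mirna_id\tgene_id"]
    for mid in sorted(target_map):
        for gid in sorted(target_map[mid]):
            lines.append(f"{mid}\t{gid}")
    return "\n".join(lines) + "\n"


def _as_buffer(source: Source) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return io.StringIO(_read_text(source))
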