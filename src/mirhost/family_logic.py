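"""Collapsing of sequence-indistinguishable mature miRNAs.

Duplicated precursors (e.g. mir-103a-1 and mir-103a-2) can produce mature
miRNAs with exactly identical sequences; short-read sequencing cannot tell
them apart, so a detected dysregulated mature must be credited to *every*
precursor — and hence every host gene — able to produce it.  Grouping is by
exact full-length sequence identity after U/T and case normalisation, never
by seed similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .errors import SequenceConflictError
from .host_assignment import CONTEXT_SENSE, HostAssignment
from .model import MirnaAnnotation

__all__ = [
    "FamilyGroup",
    "HostExpansion",
    "normalize_sequence",
    "group_indistinguishable_matures",
    "expand_family_hosts",
    "provenance_to_tsv",
]


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T) for comparison."""
    return sequence.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class FamilyGroup:
    """Matures sharing one exact sequence, and the precursors producing them.

    ``canonical_sequence`` is None for matures with no sequence available;
    those form singleton groups keyed by mature id.
    """

    canonical_sequence: Optional[str]
    mature_ids: frozenset
    precursor_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_ids", frozenset(self.mature_ids))
        object.__setattr__(self, "precursor_ids", frozenset(self.precursor_ids))


def group_indistinguishable_matures(
    mirnas: Iterable[MirnaAnnotation],
    sequences: Optional[Mapping[str, str]] = None,
) -> List[FamilyGroup]:
    """Partition matures into exact-sequence equivalence classes.

    Sequences come from the annotation itself or from an external
    ``mature_id -> sequence`` table (the table wins only by filling gaps;
    a contradiction between two sources is an error).  Matures without any
    sequence become singleton groups keyed by mature id — with no sequence
    table at all, the grouping degenerates to one group per mature id.
    """
    seq_of: Dict[str, Optional[str]] = {}
    precursors_of: Dict[str, Set[str]] = {}
    for mir in mirnas:
        for m in mir.matures:
            raw = m.sequence
            if raw is None and sequences is not None:
                raw = sequences.get(m.mature_id)
            norm = normalize_sequence(raw) if raw else None
            prev = seq_of.get(m.mature_id)
            if prev is not None and norm is not None and prev != norm:
                raise SequenceConflictError(
                    f"mature {m.mature_id} supplied with two different "
                    f"sequences ({prev} vs {norm})"
                )
            if norm is not None or m.mature_id not in seq_of:
                seq_of[m.mature_id] = norm if norm is not None else prev
            precursors_of.setdefault(m.mature_id, set()).add(mir.precursor_id)

    by_seq: Dict[str, Tuple[Set[str], Set[str]]] = {}
    groups: List[FamilyGroup] = []
    for mid in sorted(seq_of):
        seq = seq_of[mid]
        if seq is None:
            groups.append(
                FamilyGroup(None, frozenset([mid]), frozenset(precursors_of[mid]))
            )
            continue
        mats, precs = by_seq.setdefault(seq, (set(), set()))
        mats.add(mid)
        precs.update(precursors_of[mid])
    for seq in sorted(by_seq):
        mats, precs = by_seq[seq]
        groups.append(FamilyGroup(seq, frozenset(mats), frozenset(precs)))
    groups.sort(key=lambda g: (g.canonical_sequence or "", min(g.mature_ids)))
    return groups


@dataclass
class HostExpansion:
    """Result of expanding dysregulated matures to family-wide host genes."""

    gene_ids: Set[str] = field(default_factory=set)
    #: (host_gene_id, precursor_id, mature_id) per contribution
    provenance: List[Tuple[str, str, str]] = field(default_factory=list)
    unmapped: List[str] = field(default_factory=list)


def expand_family_hosts(
    mature_ids: Iterable[str],
    groups: Iterable[FamilyGroup],
    assignments: Mapping[str, HostAssignment],
) -> HostExpansion:
    """Union of sense-strand host genes over each mature's whole family.

    For every dysregulated mature, every precursor in its sequence group is
    looked up in the host assignments; intragenic-sense precursors contribute
    their host gene.  Matures absent from the annotation are collected in
    ``unmapped`` rather than raising.
    """
    by_mature: Dict[str, FamilyGroup] = {}
    for g in groups:
        for mid in g.mature_ids:
            by_mature[mid] = g

    out = HostExpansion()
    for mid in sorted(set(mature_ids)):
        group = by_mature.get(mid)
        if group is None:
            out.unmapped.append(mid)
            continue
        for pid in sorted(group.precursor_ids):
            a = assignments.get(pid)
            if a is not None and a.context == CONTEXT_SENSE:
                out.gene_ids.add(a.host_gene_id)
                out.provenance.append((a.host_gene_id, pid, mid))
    return out


def provenance_to_tsv(
    groups: Iterable[FamilyGroup],
    provenance: Iterable[Tuple[str, str, str]],
) -> str:
    """Render (host_gene_id, precursor_id, mature_id) rows with group sizes."""
    size_of = {}
    for g in groups:
        for mid in g.mature_ids:
            size_of[mid] = len(g.precursor_ids)
    lines = ["mature_id\tgroup_size\tprecursor_id\thost_gene_id"]
    for gene, prec, mid in sorted(provenance, key=lambda r: (r[2], r[1])):
        lines.append(f"{mid}\t{size_of.get(mid, 1)}\t{prec}\t{gene}")
    return "\n".join(lines) + "\n"
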