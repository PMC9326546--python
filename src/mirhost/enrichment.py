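"""Hypergeometric over-representation analysis with BH FDR control.

The query (host-gene or target-gene set) is intersected with a declared
background universe; each gene-set term is tested one-sided for
over-representation with the upper-tail hypergeometric probability
P(X >= k), X ~ Hypergeom(N, K, n), and p-values are adjusted across terms
with the Benjamini-Hochberg step-up procedure.  Depletion is deliberately
not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_MIN_TERM_SIZE = 3
DEFAULT_MAX_TERM_SIZE = 2000

MODE_HOST = "host"
MODE_TARGET = "target"


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = marked genes (term size within the universe),
    n = draws (query size within the universe), k = observed overlap.
    Delegates to :func:`scipy.stats.hypergeom.sf`, which works in log space.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n} must lie in [0, N={N}]")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"invalid overlap k={k}: must lie in [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in the input order.

    ``method`` may be ``fdr_bh`` (default) or ``bonferroni``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method=method)[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested gene-set term."""

    term_id: str
    description: str
    k: int  # overlap count
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    fold_enrichment: float
    pvalue: float
    qvalue: float
    overlap: Tuple[str, ...]
    mode: str = MODE_HOST


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
    mode: str = MODE_HOST,
    correction: str = "fdr_bh",
) -> List[EnrichmentResult]:
    """Over-representation of ``query`` in each term of ``collection``.

    Query and terms are intersected with ``universe`` before testing; terms
    outside ``[min_term_size, max_term_size]`` after intersection are not
    tested.  Results are sorted by (pvalue, term_id) so output is
    deterministic regardless of the iteration order of inputs.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query) & uni
    if not q:
        logger.warning("query is empty after universe intersection")
        return []
    N, n = len(uni), len(q)

    tested: List[Tuple[str, int, int, Tuple[str, ...]]] = []
    for term_id in sorted(collection.sets):
        members = collection.sets[term_id].members & uni
        K = len(members)
        if not (min_term_size <= K <= max_term_size):
            continue
        overlap = tuple(sorted(members & q))
        tested.append((term_id, len(overlap), K, overlap))
    if not tested:
        return []

    pvals = [hypergeom_upper_tail(k, K, n, N) for _, k, K, _ in tested]
    qvals = bh_adjust(pvals, method=correction)
    results = [
        EnrichmentResult(
            term_id=term_id,
            description=collection.sets[term_id].description,
            k=k,
            K=K,
            n=n,
            N=N,
            fold_enrichment=(k / n) / (K / N),
            pvalue=p,
            qvalue=float(qv),
            overlap=overlap,
            mode=mode,
        )
        for (term_id, k, K, overlap), p, qv in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def target_set_enrichment(
    selected_mirnas: Iterable[str],
    target_map: Mapping[str, Set[str]],
    collection: GeneSetCollection,
    universe: Iterable[str],
    **kwargs,
) -> Tuple[List[EnrichmentResult], List[str]]:
    """Comparison mode: enrichment of the pooled predicted-target set.

    The union of target genes over the selected miRNAs is fed through
    :func:`enrich` with ``mode='target'``; selected miRNAs missing from the
    target map are returned as the unmapped list.
    """
    query: Set[str] = set()
    unmapped: List[str] = []
    for mid in sorted(set(selected_mirnas)):
        targets = target_map.get(mid)
        if targets is None:
            unmapped.append(mid)
        else:
            query |= set(targets)
    if not query:
        return [], unmapped
    return enrich(query, collection, universe, mode=MODE_TARGET, **kwargs), unmapped


def enrichment_to_tsv(results: Iterable[EnrichmentResult]) -> str:
    header = (
        "term_id\tdescription\tk\tK\tn\tN\tfold_enrichment\tpvalue\tqvalue"
        "\toverlap\tmode"
    )
    lines = [header]
    for r in results:
        lines.append(
            f"{r.term_id}\t{r.description}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
            f"{r.fold_enrichment:.6g}\t{r.pvalue:.6g}\t{r.qvalue:.6g}\t"
            f"{','.join(r.overlap) or '.'}\t{r.mode}"
        )
    return "\n".join(lines) + "\n"
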