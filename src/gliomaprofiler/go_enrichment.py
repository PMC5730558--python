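"""Rank-based GO-term enrichment from a gene → log2-fold-change list.

Genes are ranked by signed log2 fold change and each term's annotated genes
are compared against all remaining input genes with a two-sided rank-sum
(Mann-Whitney) test — exact null distribution for small tie-free instances,
tie-corrected normal approximation otherwise — followed by Benjamini-Hochberg
correction across tested terms.  Because the statistic depends only on ranks,
any strictly increasing transform of the fold changes leaves every p-value
unchanged.

Annotations are consumed flat (no GO-graph propagation) and are typically
restricted to the biological_process namespace upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._stats import bh_adjust, mann_whitney
from .datatypes import ValidationError

log = logging.getLogger(__name__)

DEFAULT_MIN_TERM_SIZE = 3
DEFAULT_TOP_K = 30

#: statistic identification carried into output headers
STATISTIC_NOTE = (
    "two-sided rank-sum (Mann-Whitney) test on signed log2 fold-change ranks; "
    "Benjamini-Hochberg correction"
)


@dataclass
class GOAnnotation:
    """One GO term: id, human-readable name, namespace and annotated genes."""

    term_id: str
    name: str
    genes: set
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r} has an empty gene set")
        self.genes = set(self.genes)


@dataclass
class GOResult:
    term_id: str
    name: str
    n_in: int
    statistic: float
    p: float
    q: float
    direction: str
    median_log2fc: float


def _as_annotations(annotation) -> list[GOAnnotation]:
    if isinstance(annotation, dict):
        return [GOAnnotation(t, t, set(g)) for t, g in annotation.items()]
    return list(annotation)


def rank_enrichment(
    gene_fc: dict[str, float],
    annotation,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    namespace: str | None = None,
) -> list[GOResult]:
    """Rank-sum enrichment of every annotated term against the input list.

    Parameters
    ----------
    gene_fc
        Mapping gene → signed log2 fold change (the full input list; apply
        any up-regulation pre-filter before calling).
    annotation
        Iterable of :class:`GOAnnotation` or a plain ``{term: gene_set}``
        mapping.
    min_term_size
        Terms with fewer input genes than this are skipped.
    namespace
        When given, only terms of this namespace are tested.

    Returns results sorted by p ascending, BH-adjusted across the tested
    terms.  A term whose genes are all absent from the input is skipped with
    a log entry; a term covering the entire input carries no rank information
    and gets p = 1.
    """
    if not gene_fc:
        raise ValidationError("empty input gene list")
    terms = _as_annotations(annotation)
    if namespace is not None:
        terms = [t for t in terms if t.namespace == namespace]
    genes = np.array(list(gene_fc.keys()))
    fc = np.array([gene_fc[g] for g in genes], dtype=float)

    tested, stats_rows = [], []
    for term in terms:
        mask = np.isin(genes, list(term.genes))
        n_in = int(mask.sum())
        if n_in == 0:
            log.info("term %s: no annotated gene in input; skipped", term.term_id)
            continue
        if n_in < min_term_size:
            log.info("term %s: only %d gene(s) in input (< %d); skipped",
                     term.term_id, n_in, min_term_size)
            continue
        in_fc, out_fc = fc[mask], fc[~mask]
        if out_fc.size == 0:
            u, p = float(n_in * 0 / 2), 1.0  # term covers whole input
        else:
            u, p = mann_whitney(in_fc, out_fc)
        direction = "up" if np.median(in_fc) > np.median(fc) else "down"
        tested.append(term)
        stats_rows.append((n_in, u, p, direction, float(np.median(in_fc))))
    if len(tested) < 2:
        raise ValidationError(
            "fewer than 2 terms remain after size filtering; nothing to rank"
        )
    q = bh_adjust([row[2] for row in stats_rows])
    results = [
        GOResult(term_id=t.term_id, name=t.name, n_in=row[0], statistic=row[1],
                 p=row[2], q=float(qv), direction=row[3], median_log2fc=row[4])
        for t, row, qv in zip(tested, stats_rows, q)
    ]
    results.sort(key=lambda r: (r.p, -r.n_in, r.term_id))
    return results


def summarize_terms(
    results: list[GOResult], direction: str, k: int = DEFAULT_TOP_K
) -> list[GOResult]:
    """Top-K terms of one direction, sorted by p ascending (ties broken by
    larger n_in then term id)."""
    if k < 1:
        raise ValidationError("K must be at least 1")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    chosen = [r for r in results if r.direction == direction]
    chosen.sort(key=lambda r: (r.p, -r.n_in, r.term_id))
    return chosen[:k]


# re-export: BH adjustment is part of this module's public surface
__all__ = [
    "GOAnnotation",
    "GOResult",
    "rank_enrichment",
    "summarize_terms",
    "bh_adjust",
    "STATISTIC_NOTE",
]
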