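"""Cross-species glioma-subtype similarity scoring.

The headline analysis of the pipeline: human tumor samples are assigned to
glioblastoma subtypes (Proneural, Neural, Classical, Mesenchymal) with a
one-sample Kolmogorov-Smirnov statistic over the within-sample normalized
ranks of each subtype's signature genes; rat genes are mapped to human
orthologues through a one-to-one-filtered symbol map; per-replicate rat
tumor/normal log2 fold-change vectors are then correlated (Spearman) with
each subtype's mean human fold-change vector over the mapped signature
genes, and subtypes are ranked by mean correlation with pairwise two-sided
Mann-Whitney tests between their correlation lists.

Assignment rule: genes are ranked within each sample with the most highly
expressed gene at rank 1; a subtype whose signature is coherently
over-expressed pushes its normalized signature-gene ranks toward 0, which the
upward-signed KS statistic D+ measures.  The subtype with the largest D+
wins; all four D (and exact two-sided p) values are always reported so
alternative rules can be audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney, spearman
from .datatypes import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)

#: below this per-group size the pairwise Mann-Whitney p cannot go under 0.1
SMALL_SAMPLE_N = 4


@dataclass
class SignatureSet:
    """Subtype → gene list; lists must be pairwise disjoint, ≥3 genes each."""

    subtype_genes: dict[str, list]

    def __post_init__(self) -> None:
        seen: set = set()
        for subtype, genes in self.subtype_genes.items():
            genes = list(genes)
            if len(genes) < 3:
                raise ValidationError(f"subtype {subtype!r} has fewer than 3 genes")
            overlap = seen & set(genes)
            if overlap:
                raise ValidationError(
                    f"signature gene(s) shared between subtypes: "
                    f"{sorted(overlap)[:5]}"
                )
            seen |= set(genes)
            self.subtype_genes[subtype] = genes

    @property
    def subtypes(self) -> list[str]:
        return list(self.subtype_genes)

    @property
    def all_genes(self) -> list:
        return [g for genes in self.subtype_genes.values() for g in genes]

    def __len__(self) -> int:
        return len(self.all_genes)


@dataclass
class OrthologMap:
    """Rat→human symbol pairs, filtered to a one-to-one correspondence.

    Pairs in which either symbol participates in more than one pairing are
    dropped (and counted), keeping downstream correlation gene sets
    well-defined.
    """

    pairs: list[tuple]
    n_dropped_ambiguous: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        rat_counts: dict = {}
        human_counts: dict = {}
        for r, h in self.pairs:
            rat_counts[r] = rat_counts.get(r, 0) + 1
            human_counts[h] = human_counts.get(h, 0) + 1
        kept = [
            (r, h)
            for r, h in self.pairs
            if rat_counts[r] == 1 and human_counts[h] == 1
        ]
        self.n_dropped_ambiguous = len(self.pairs) - len(kept)
        if self.n_dropped_ambiguous:
            log.info("ortholog map: dropped %d ambiguous pair(s)",
                     self.n_dropped_ambiguous)
        self.pairs = kept
        self.rat_to_human = dict(kept)
        self.human_to_rat = {h: r for r, h in kept}


@dataclass
class SubtypeAssignment:
    """Per-sample subtype call plus the full KS audit trail.

    ``ks_table`` rows are (sample, subtype) with columns D_up (upward-signed
    D+), D (two-sided statistic) and p (exact two-sided KS p); samples where
    no subtype shows an upward shift (all D+ ≤ D−) are still assigned the
    max-D+ subtype but listed in ``low_confidence``.
    """

    assignments: dict[str, str]
    ks_table: pd.DataFrame
    low_confidence: list[str] = field(default_factory=list)

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s, st in self.assignments.items() if st == subtype]


@dataclass
class SimilarityResult:
    """Per-subtype Spearman correlations of rat fold changes with the human
    subtype reference, with pairwise rank tests and the winning subtype."""

    rho: dict[str, list]
    mean_rho: dict[str, float]
    sd_rho: dict[str, float]
    pairwise_p: dict[tuple, float]
    ranking: list[str]
    winner: str
    n_genes: int
    excluded_subtypes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _ks_one_sample_uniform(u: np.ndarray) -> tuple[float, float, float]:
    """One-sample KS of values ``u`` in (0,1) against Uniform(0,1).

    Returns (D+, D, p) where D+ = sup(ECDF − uniform CDF) measures a shift
    toward small values, D = max(D+, D−), and p is the exact two-sided
    KS p-value for n = len(u).
    """
    u = np.sort(np.asarray(u, dtype=float))
    n = len(u)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - u))
    d_minus = float(np.max(u - (i - 1) / n))
    d = max(d_plus, d_minus)
    p = float(stats.kstwo.sf(d, n))
    return d_plus, d, p


def assign_subtypes(human: ExpressionStudy, sig: SignatureSet) -> SubtypeAssignment:
    """Assign every tumor sample to the subtype with the largest upward
    one-sample KS statistic over normalized signature-gene ranks.

    Within each sample all genes are ranked by expression (rank 1 = highest,
    average ranks for ties) and normalized as rank/(G+1); each subtype's
    signature genes' normalized ranks are tested against Uniform(0,1).
    """
    tumors = human.tumor_samples
    if not tumors:
        raise ValidationError("cohort contains no tumor samples")
    gene_index = {g: i for i, g in enumerate(human.genes)}
    present = {
        subtype: [gene_index[g] for g in genes if g in gene_index]
        for subtype, genes in sig.subtype_genes.items()
    }
    for subtype, idx in present.items():
        if len(idx) < 3:
            raise ValidationError(
                f"subtype {subtype!r}: fewer than 3 signature genes present "
                "in the expression matrix"
            )
    matrix = human.matrix.to_numpy(dtype=float)
    n_genes = matrix.shape[0]
    assignments, rows, low_conf = {}, [], []
    for sample in tumors:
        col = matrix[:, human.samples.get_loc(sample)]
        # rank 1 = most highly expressed; average ranks for ties
        ranks = stats.rankdata(-col, method="average")
        norm = ranks / (n_genes + 1)
        best, best_dplus, any_up = None, -np.inf, False
        for subtype, idx in present.items():
            d_plus, d, p = _ks_one_sample_uniform(norm[idx])
            rows.append({"sample": sample, "subtype": subtype,
                         "D_up": d_plus, "D": d, "p": p})
            if d_plus >= d - 1e-15:  # upward shift dominates
                any_up = True
            if d_plus > best_dplus:
                best, best_dplus = subtype, d_plus
        assignments[sample] = best
        if not any_up:
            low_conf.append(sample)
    return SubtypeAssignment(
        assignments=assignments,
        ks_table=pd.DataFrame(rows),
        low_confidence=low_conf,
    )


def map_orthologs(genes, ortholog_map: OrthologMap) -> list[tuple]:
    """Restrict the (already one-to-one) map to the given rat gene list.

    Returns rat→human pairs; unmapped genes are counted and logged; an empty
    intersection raises.
    """
    genes = list(genes)
    pairs = [(g, ortholog_map.rat_to_human[g])
             for g in genes if g in ortholog_map.rat_to_human]
    n_unmapped = len(genes) - len(pairs)
    if n_unmapped:
        log.info("map_orthologs: %d of %d gene(s) had no one-to-one orthologue",
                 n_unmapped, len(genes))
    if not pairs:
        raise ValidationError("no input gene has a one-to-one orthologue")
    return pairs


def fold_change_vector(
    study: ExpressionStudy, per_sample: bool = False
) -> pd.DataFrame:
    """Tumor/normal log2 fold changes against the mean of normals.

    ``per_sample=False`` returns a single-column frame (tumor-group mean −
    control mean); ``per_sample=True`` one column per tumor sample.  The
    per-sample columns average (over tumors) to the group-mean vector.
    """
    controls = study.control_samples
    if not controls:
        raise ValidationError("fold changes need at least one control/normal sample")
    reference = study.matrix[controls].mean(axis=1)
    tumors = study.tumor_samples
    if not tumors:
        raise ValidationError("no tumor samples")
    if per_sample:
        return study.matrix[tumors].sub(reference, axis=0)
    return (study.matrix[tumors].mean(axis=1) - reference).to_frame("log2fc")


def similarity_ranking(
    rat_fcs: pd.DataFrame,
    human_fcs: pd.DataFrame,
    assignment: SubtypeAssignment,
    mapped_pairs: list[tuple],
) -> SimilarityResult:
    """Rank subtypes by mean Spearman correlation with the rat model.

    Each subtype's reference vector is the mean human per-sample fold change
    over the samples assigned to it; each rat replicate column of ``rat_fcs``
    is correlated with every reference over the mapped gene pairs.  Pairwise
    two-sided Mann-Whitney tests compare subtypes' correlation lists; with
    the usual 3 rat replicates these cannot fall below p = 0.1, which is
    flagged as a warning.  Subtypes with no assigned samples are excluded
    from the ranking and flagged.
    """
    if rat_fcs.shape[1] < 1:
        raise ValidationError("need at least one rat replicate fold-change vector")
    pairs = [(r, h) for r, h in mapped_pairs
             if r in rat_fcs.index and h in human_fcs.index]
    if len(pairs) < 3:
        raise ValidationError("fewer than 3 mapped genes shared by both studies")
    rat_rows = [r for r, _ in pairs]
    human_rows = [h for _, h in pairs]

    subtypes = sorted({st for st in assignment.assignments.values() if st})
    warnings, excluded = [], []
    rho: dict[str, list] = {}
    for subtype in subtypes:
        samples = [s for s in assignment.samples_of(subtype)
                   if s in human_fcs.columns]
        if not samples:
            excluded.append(subtype)
            continue
        reference = human_fcs[samples].mean(axis=1).loc[human_rows].to_numpy()
        rho[subtype] = [
            spearman(rat_fcs[col].loc[rat_rows].to_numpy(), reference)
            for col in rat_fcs.columns
        ]
    if not rho:
        raise ValidationError("no subtype received any assigned sample")
    mean_rho = {s: float(np.mean(v)) for s, v in rho.items()}
    sd_rho = {s: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
              for s, v in rho.items()}
    n_rep = rat_fcs.shape[1]
    if n_rep < SMALL_SAMPLE_N:
        warnings.append(
            f"only {n_rep} rat replicate(s): two-sided Mann-Whitney p cannot "
            f"fall below {2.0 / math.comb(2 * n_rep, n_rep):.3g}"
        )
    pairwise_p = {}
    for a, b in combinations(sorted(rho), 2):
        if len(rho[a]) >= 1 and len(rho[b]) >= 1:
            _, p = mann_whitney(rho[a], rho[b])
            pairwise_p[(a, b)] = p
    ranking = sorted(mean_rho, key=lambda s: (-mean_rho[s], s))
    return SimilarityResult(
        rho=rho, mean_rho=mean_rho, sd_rho=sd_rho, pairwise_p=pairwise_p,
        ranking=ranking, winner=ranking[0], n_genes=len(pairs),
        excluded_subtypes=excluded, warnings=warnings,
    )
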