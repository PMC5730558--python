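"""Gene-level differential expression between control and glioma groups.

The testing model is deliberately plain, matching desk analysis of a small
microarray study: per-gene Welch two-sided t-tests on log2 expression,
discoveries at a uniform alpha level, and the plug-in false-discovery-rate
estimate

    FDR_hat = m * alpha / k

(expected false positives over observed discoveries, with m genes tested and
k discoveries).  Benjamini-Hochberg q-values are emitted per gene alongside
for transparency, but the headline FDR is the plug-in estimate.

Also provided: probe→gene aggregation (uniquely-mapping probes averaged per
gene), control-centred matrices for heatmaps, top-K strongest-regulation
lists, and M1/M2/GAM marker-panel reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .datatypes import CONTROL, TUMOR, ExpressionStudy, ValidationError

DEFAULT_ALPHA = 0.01
DEFAULT_TOP_K = 50


@dataclass
class ProbeAnnotation:
    """Probe id → set of gene symbols (possibly empty or multiple)."""

    mapping: dict[str, set]

    def __post_init__(self) -> None:
        self.mapping = {p: set(g) for p, g in self.mapping.items()}


@dataclass
class AggregationReport:
    n_probes: int
    n_unique: int
    n_multi: int
    n_unmapped: int
    n_genes: int


@dataclass
class DEResult:
    """Per-gene Welch test results plus discovery accounting.

    ``table`` columns: gene (index), log2fc (mean tumor − mean control),
    t, df (Welch–Satterthwaite), p, q (BH), significant, direction.
    """

    table: pd.DataFrame
    alpha: float
    m: int
    k: int
    n_up: int
    n_down: int
    fdr_hat: float | None

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "m": self.m,
            "k": self.k,
            "up": self.n_up,
            "down": self.n_down,
            "fdr_hat": self.fdr_hat,
        }


@dataclass
class MarkerPanel:
    """An ordered marker gene panel (e.g. M1, M2 or glioma-associated
    microglia/macrophage signature genes)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("marker panel must not be empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate genes in panel {self.name!r}")


def aggregate_probes(
    probe_matrix: pd.DataFrame,
    annotation: ProbeAnnotation,
    groups: pd.Series,
) -> tuple[ExpressionStudy, AggregationReport]:
    """Collapse a probes × samples matrix to genes × samples.

    Only probes mapping to exactly one gene are retained; a gene's value is
    the arithmetic mean of its retained probes, per sample.  Multi-mapping
    and unmapped probes are dropped and counted in the report.
    """
    if probe_matrix.index.duplicated().any():
        raise ValidationError("duplicate probe identifiers in matrix")
    unique_map, n_multi, n_unmapped = {}, 0, 0
    for probe in probe_matrix.index:
        genes = annotation.mapping.get(probe, set())
        if len(genes) == 1:
            unique_map[probe] = next(iter(genes))
        elif len(genes) == 0:
            n_unmapped += 1
        else:
            n_multi += 1
    if not unique_map:
        raise ValidationError("no probe maps uniquely to a gene")
    kept = probe_matrix.loc[list(unique_map)]
    gene_matrix = kept.groupby(pd.Series(unique_map), sort=True).mean()
    gene_matrix.index.name = "gene"
    report = AggregationReport(
        n_probes=len(probe_matrix),
        n_unique=len(unique_map),
        n_multi=n_multi,
        n_unmapped=n_unmapped,
        n_genes=len(gene_matrix),
    )
    return ExpressionStudy(gene_matrix, groups), report


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorised row-wise Welch test of a (genes × n1) vs b (genes × n2).

    Rows where both groups have zero variance follow the documented
    convention: equal means → t = 0, p = 1; unequal means → ±inf, p = 0.
    """
    from scipy import stats

    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    df[degenerate] = n1 + n2 - 2
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), np.where(degenerate, 1, df))
    )
    p[degenerate & (diff == 0)] = 1.0
    return diff, t, df, p


def estimate_fdr(m: int, k: int, alpha: float) -> float:
    """Plug-in FDR estimate m·alpha/k at a uniform alpha level."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    if k < 1:
        raise ValidationError("FDR_hat is undefined when there are no discoveries")
    if k > m:
        raise ValidationError("discoveries cannot exceed genes tested")
    return m * alpha / k


def welch_de(study: ExpressionStudy, alpha: float = DEFAULT_ALPHA) -> DEResult:
    """Per-gene Welch two-sided t-test of tumor vs control.

    Discoveries are genes with p < ``alpha``; direction is the sign of
    log2fc (tumor mean − control mean).  The plug-in FDR_hat = m·alpha/k is
    attached (None when k = 0, flagged rather than divided by zero).
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    study.require_group_sizes(2)
    tumor = study.matrix[study.tumor_samples].to_numpy(dtype=float)
    control = study.matrix[study.control_samples].to_numpy(dtype=float)
    log2fc, t, df, p = _welch_arrays(tumor, control)
    q = bh_adjust(p)
    significant = p < alpha
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": direction,
        },
        index=study.genes,
    )
    m = len(table)
    k = int(significant.sum())
    n_up = int(np.sum(significant & (log2fc > 0)))
    n_down = int(np.sum(significant & (log2fc < 0)))
    fdr_hat = estimate_fdr(m, k, alpha) if k > 0 else None
    return DEResult(table=table, alpha=alpha, m=m, k=k,
                    n_up=n_up, n_down=n_down, fdr_hat=fdr_hat)


def center_on_control(study: ExpressionStudy) -> pd.DataFrame:
    """Centre each gene's log2 profile on its control-group mean, the heatmap
    convention in which colour encodes log2(ratio) versus control.  Idempotent;
    leaves between-group differences unchanged."""
    controls = study.control_samples
    if not controls:
        raise ValidationError("no control samples to centre on")
    centred = study.matrix.sub(study.matrix[controls].mean(axis=1), axis=0)
    return centred


def top_regulated(
    result: DEResult, k: int = DEFAULT_TOP_K, by: str = "fold_change"
) -> pd.DataFrame:
    """The K most strongly regulated discoveries.

    Default ranking is |log2fc| descending among significant genes, ties
    broken by smaller p then lexicographic gene id; ``by="p"`` ranks by p
    ascending instead.  Returns all discoveries when K exceeds their number.
    """
    if k < 1:
        raise ValidationError("K must be at least 1")
    if by not in ("fold_change", "p"):
        raise ValidationError("ranking must be 'fold_change' or 'p'")
    disc = result.table[result.table["significant"]].copy()
    disc["_absfc"] = disc["log2fc"].abs()
    disc["_gene"] = disc.index
    if by == "fold_change":
        disc = disc.sort_values(
            ["_absfc", "p", "_gene"], ascending=[False, True, True],
            kind="mergesort",
        )
    else:
        disc = disc.sort_values(
            ["p", "_absfc", "_gene"], ascending=[True, False, True],
            kind="mergesort",
        )
    return disc.drop(columns=["_absfc", "_gene"]).head(k)


def linear_fold_change(log2fc: float) -> float:
    """Signed linear fold change: 2**log2fc for upregulation, −2**|log2fc|
    for downregulation (−2 means halved).  0 maps to 1 (no change)."""
    if log2fc >= 0:
        return float(2.0**log2fc)
    return float(-(2.0 ** (-log2fc)))


def marker_panel_report(result: DEResult, panel: MarkerPanel) -> pd.DataFrame:
    """Per-panel-gene report (gene, fold_change, p, direction, significant,
    missing), in panel order.

    Fold change uses the signed linear convention (see
    :func:`linear_fold_change`); genes absent from the study are flagged
    missing rather than raising.
    """
    rows = []
    for gene in panel.genes:
        if gene in result.table.index:
            rec = result.table.loc[gene]
            rows.append(
                {
                    "gene": gene,
                    "panel": panel.name,
                    "log2fc": float(rec["log2fc"]),
                    "fold_change": linear_fold_change(float(rec["log2fc"])),
                    "p": float(rec["p"]),
                    "direction": rec["direction"],
                    "significant": bool(rec["significant"]),
                    "missing": False,
                }
            )
        else:
            rows.append(
                {
                    "gene": gene,
                    "panel": panel.name,
                    "log2fc": np.nan,
                    "fold_change": np.nan,
                    "p": np.nan,
                    "direction": "none",
                    "significant": False,
                    "missing": True,
                }
            )
    return pd.DataFrame(rows)


def apply_filters(
    result: DEResult,
    max_p: float | None = None,
    min_abs_log2fc: float | None = None,
    fold_change_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Composable post-hoc discovery filters.

    ``fold_change_window`` keeps genes whose signed *linear* fold change lies
    outside the window (e.g. ``(-5, 5)`` keeps |linear FC| ≥ 5); ``max_p``
    and ``min_abs_log2fc`` are straightforward cutoffs.  These reproduce the
    alternative selection rules sometimes layered on top of the uniform-alpha
    criterion.
    """
    table = result.table
    mask = pd.Series(True, index=table.index)
    if max_p is not None:
        mask &= table["p"] < max_p
    if min_abs_log2fc is not None:
        mask &= table["log2fc"].abs() >= min_abs_log2fc
    if fold_change_window is not None:
        lo, hi = fold_change_window
        linear = table["log2fc"].map(linear_fold_change)
        mask &= (linear <= lo) | (linear >= hi)
    return table[mask]
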