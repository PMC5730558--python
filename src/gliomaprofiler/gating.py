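"""Quadrant-gate analysis of immune-cell flow-cytometry panels.

The workflow mirrors manual FACS analysis of a glioma immune infiltrate:

1. derive per-channel positivity cutoffs from a matched isotype-control
   table (default: its 99th percentile), and for CD45 additionally a
   low/high split at the density valley between the two dominant modes of
   the positive events' log-intensities;
2. assign each event to a population by strict threshold comparisons —
   microglia CD11b+CD45low, blood-derived macrophages CD11b+CD45high,
   leukocytes CD11b-CD45high, MDSCs CD11b+Gr1+, and single-marker T-cell
   subsets (CD4+, CD8a+, FOXP3+);
3. report population fractions over all gated events, glioma/sham kinetics
   ratios, and two-group comparisons (Welch t followed by Mann-Whitney U).

Events exactly equal to a threshold are classified negative (strict
inequality throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from ._stats import mann_whitney, welch_t
from .datatypes import EventTable, ValidationError

DEFAULT_POS_QUANTILE = 0.99

MYELOID_POPULATIONS = ("microglia", "macrophage", "leukocyte", "unclassified")
TCELL_MARKERS = ("CD4", "CD8a", "FOXP3")


class GatingError(ValueError):
    """Gate derivation failed in a way requiring manual intervention."""


@dataclass
class GateThresholds:
    """Per-channel positivity cutoffs plus the CD45 low/high separator.

    ``positive`` maps channel → θ_pos (intensity units); events strictly above
    θ_pos are positive.  ``cd45_split`` (θ_split) separates CD45-low from
    CD45-high among positive events and must exceed θ_pos for CD45.
    """

    positive: dict[str, float]
    cd45_split: float | None = None

    def __post_init__(self) -> None:
        for ch, theta in self.positive.items():
            if not np.isfinite(theta) or theta <= 0:
                raise ValidationError(f"θ_pos for {ch!r} must be finite and positive")
        if self.cd45_split is not None:
            if "CD45" not in self.positive:
                raise ValidationError("cd45_split given without a CD45 θ_pos")
            if self.cd45_split <= self.positive["CD45"]:
                raise ValidationError("θ_split must exceed the CD45 θ_pos")

    def require_split(self) -> float:
        if self.cd45_split is None:
            raise ValidationError("thresholds lack the CD45 low/high split")
        return self.cd45_split


@dataclass
class PopulationFractions:
    """Event counts and all-gated-event fractions per population."""

    counts: dict[str, int]
    total: int
    conditional: dict[str, float] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        return {name: n / self.total for name, n in self.counts.items()}

    def fraction(self, name: str) -> float:
        return self.counts[name] / self.total

    def percent(self, name: str) -> float:
        return 100.0 * self.fraction(name)


@dataclass
class KineticsResult:
    """Glioma/sham fraction ratios per population for one time point."""

    day: int | None
    ratios: dict[str, float]
    undefined: list[str]


@dataclass
class GroupComparison:
    """Welch t and Mann-Whitney U comparison of two groups of fractions.

    The significance flag follows the Mann-Whitney p at the 0.05 level, the
    convention of reporting the t test 'followed by' the distribution-free
    test."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    welch_t: float
    welch_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    significant: bool


#: a candidate mode pair is accepted only if the valley between the two peaks
#: drops below this fraction of the smaller peak's density; KDE wiggles on a
#: genuinely unimodal distribution fail this prominence requirement
_VALLEY_PROMINENCE = 0.8
#: local maxima below this fraction of the global density maximum are ignored
_MIN_PEAK_HEIGHT = 0.05


def _min_density_split(log_values: np.ndarray, grid_size: int = 512) -> float:
    """Valley (minimum-density point) between the two largest modes of a 1-D
    sample, found on a Gaussian-KDE density grid.  Raises GatingError when the
    density has fewer than two sufficiently prominent modes."""
    kde = gaussian_kde(log_values)
    lo, hi = log_values.min(), log_values.max()
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[dens[peaks] >= _MIN_PEAK_HEIGHT * dens.max()]
    unimodal = GatingError(
        "CD45-positive events look unimodal; cannot derive a low/high "
        "split automatically — supply cd45_split manually"
    )
    if len(peaks) < 2:
        raise unimodal
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + int(np.argmin(dens[left:right + 1]))
    if dens[valley] >= _VALLEY_PROMINENCE * min(dens[left], dens[right]):
        raise unimodal
    return float(grid[valley])


def derive_thresholds(
    stained: EventTable,
    isotype: EventTable,
    pos_quantile: float = DEFAULT_POS_QUANTILE,
    cd45_split: float | None = None,
) -> GateThresholds:
    """Derive positivity cutoffs from the isotype control and, when the panel
    carries CD45, the low/high split from the stained events.

    θ_pos per channel is the ``pos_quantile`` quantile (default 0.99) of the
    isotype-control intensity distribution — the background-staining
    definition of positivity.  θ_split is the minimum-density point between
    the two largest modes of log-intensity among CD45-positive stained
    events; pass ``cd45_split`` to override (or to supply it when the
    distribution is unimodal).
    """
    if not (0.0 < pos_quantile < 1.0):
        raise ValidationError("pos_quantile must be in (0, 1)")
    if isotype.n_events < 100:
        raise ValidationError(
            f"isotype control has only {isotype.n_events} events; "
            "at least 100 are required for a stable quantile"
        )
    stained.require_channels(isotype.channels)
    positive = {
        ch: float(np.quantile(isotype.data[ch].to_numpy(), pos_quantile))
        for ch in isotype.channels
    }
    split = cd45_split
    if split is None and "CD45" in stained.data.columns:
        cd45 = stained.data["CD45"].to_numpy()
        pos_events = cd45[cd45 > positive["CD45"]]
        if len(pos_events) >= 10:
            split = float(np.exp(_min_density_split(np.log(pos_events))))
    return GateThresholds(positive=positive, cd45_split=split)


def classify_myeloid(events: EventTable, th: GateThresholds) -> PopulationFractions:
    """Quadrant-gate the CD11b/CD45 panel.

    microglia: CD11b+ and θ_pos < CD45 ≤ θ_split; macrophage: CD11b+ and
    CD45 > θ_split; leukocyte: CD11b- and CD45 > θ_split; everything else is
    unclassified.  Fractions are over all gated events.
    """
    events.require_channels(["CD11b", "CD45"])
    split = th.require_split()
    cd11b = events.data["CD11b"].to_numpy()
    cd45 = events.data["CD45"].to_numpy()
    cd11b_pos = cd11b > th.positive["CD11b"]
    cd45_pos = cd45 > th.positive["CD45"]
    cd45_high = cd45 > split
    cd45_low = cd45_pos & ~cd45_high
    counts = {
        "microglia": int(np.sum(cd11b_pos & cd45_low)),
        "macrophage": int(np.sum(cd11b_pos & cd45_high)),
        "leukocyte": int(np.sum(~cd11b_pos & cd45_high)),
    }
    counts["unclassified"] = events.n_events - sum(counts.values())
    return PopulationFractions(counts=counts, total=events.n_events)


def classify_tcell_panel(
    events: EventTable, th: GateThresholds, marker: str
) -> PopulationFractions:
    """Single-marker positive fraction for one T-cell subset.

    ``marker`` selects CD4 (Th), CD8a (Tc) or FOXP3 (Treg); the fraction is
    events above that channel's θ_pos over all gated events.
    """
    if marker not in TCELL_MARKERS:
        raise ValidationError(
            f"unknown T-cell marker {marker!r}; supported: {TCELL_MARKERS}"
        )
    events.require_channels([marker])
    values = events.data[marker].to_numpy()
    n_pos = int(np.sum(values > th.positive[marker]))
    counts = {f"{marker}_pos": n_pos, "negative": events.n_events - n_pos}
    return PopulationFractions(counts=counts, total=events.n_events)


def classify_mdsc(events: EventTable, th: GateThresholds) -> PopulationFractions:
    """CD11b+Gr1+ double-positive (MDSC) fraction over all gated events, plus
    the conditional Gr1+ fraction within CD11b+ events (flagged undefined when
    no event is CD11b+)."""
    events.require_channels(["CD11b", "Gr1"])
    cd11b_pos = events.data["CD11b"].to_numpy() > th.positive["CD11b"]
    gr1_pos = events.data["Gr1"].to_numpy() > th.positive["Gr1"]
    n_dp = int(np.sum(cd11b_pos & gr1_pos))
    n_cd11b = int(np.sum(cd11b_pos))
    counts = {"mdsc": n_dp, "cd11b_pos": n_cd11b}
    result = PopulationFractions(counts=counts, total=events.n_events)
    if n_cd11b > 0:
        result.conditional["gr1_pos_within_cd11b_pos"] = n_dp / n_cd11b
    else:
        result.undefined.append("gr1_pos_within_cd11b_pos")
    return result


def kinetics_ratio(
    glioma: PopulationFractions,
    sham: PopulationFractions,
    day: int | None = None,
    populations=None,
) -> KineticsResult:
    """Glioma-to-sham content ratio per population.

    A population with zero sham fraction is flagged undefined rather than
    reported as infinity.
    """
    if populations is None:
        populations = [p for p in glioma.counts if p in sham.counts]
    missing = [p for p in populations if p not in glioma.counts or p not in sham.counts]
    if missing:
        raise ValidationError(f"population(s) absent from one side: {missing}")
    ratios, undefined = {}, []
    for pop in populations:
        fs = sham.fraction(pop)
        if fs == 0:
            undefined.append(pop)
        else:
            ratios[pop] = glioma.fraction(pop) / fs
    return KineticsResult(day=day, ratios=ratios, undefined=undefined)


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Compare two groups of per-animal fractions: Welch two-sided t-test
    followed by the two-sided Mann-Whitney U test (exact for combined n ≤ 20
    without ties, tie-corrected normal approximation otherwise).  The
    significance flag is Mann-Whitney p < ``alpha``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    t, _, p_t = welch_t(a, b)
    u, p_u = mann_whitney(a, b)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(len(x)))  # noqa: E731
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b), n_a=len(a), n_b=len(b),
        welch_t=t, welch_p=p_t,
        mannwhitney_u=u, mannwhitney_p=p_u,
        significant=bool(p_u < alpha),
    )
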