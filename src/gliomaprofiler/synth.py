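"""Seeded generators for every input the pipeline consumes.

The generators emulate the three kinds of raw material a rat C6-glioma
immune-microenvironment study produces:

* flow-cytometry event tables (log-normal fluorescence mixtures with
  condition-specific population fractions, plus matched isotype controls),
* two-group log2 expression matrices with planted differential effects and
  planted enriched GO terms,
* a human tumor/normal cohort with four planted glioblastoma-subtype
  centroids, a four-subtype gene signature, a rat→human ortholog map with
  configurable retention, and a rat study whose fold-change profile carries
  one target subtype's (attenuated) centroid.

Every generator takes a single integer seed and is bit-reproducible.
Sub-streams are derived with ``numpy.random.SeedSequence(seed,
spawn_key=(k,))`` for fixed per-purpose indices ``k``, so adding a new
generator call never perturbs the streams of earlier ones.  Planted ground
truth is always returned as a separate record (and written to a sidecar file
by the pipeline), never embedded in the data tables.

Default population fractions are the percentages the emulated study reports:
13% microglia in sham brains; 28% microglia, 4% macrophages and 20%
leukocytes at day 21 in glioma-bearing brains; 8.20% FOXP3+ Tregs and 2.80%
CD4+ Th cells in glioma-bearing hemispheres; CD11b+Gr1+ MDSCs at 1.05→3.99%
(brain) and 2.11→6.30% (blood) from sham to glioma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CONTROL, TUMOR, EventTable, ExpressionStudy, ValidationError

# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

# fixed stream indices; new purposes append, existing ones never renumber
STREAM_STAINED = 0
STREAM_ISOTYPE = 1
STREAM_EXPRESSION = 2
STREAM_COHORT = 3
STREAM_ANNOTATION = 4


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Derive an independent generator for purpose-stream ``stream``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def child_seed(seed: int, stream: int) -> int:
    """A derived integer seed (< 2**31) for handing to another generator."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# fluorescence panel simulation
# ---------------------------------------------------------------------------

# Canonical log-intensity levels (natural log of arbitrary linear units).
# Negative events sit at the autofluorescence level; the isotype control sits
# slightly above it because isotype antibodies carry low-level nonspecific
# binding; positive populations are well separated from the 99th-percentile
# positivity cutoff the gating module derives from the isotype table.
NEGATIVE_LOG_MEAN = 3.0
NEGATIVE_LOG_SD = 0.3
ISOTYPE_LOG_OFFSET = 0.2
ISOTYPE_LOG_SD = 0.4
POSITIVE_LOG_MEAN = 7.0
POSITIVE_LOG_SD = 0.5
# CD45 is bimodal among positive events: microglia are CD45-low, peripheral
# immune cells CD45-high; the 3-log-unit gap makes the valley learnable.
CD45_LOW_LOG_MEAN = 5.5
CD45_HIGH_LOG_MEAN = 8.5
CD45_LOG_SD = 0.45


@dataclass
class PopulationSpec:
    """One mixture component: a named population with per-channel log-normal
    parameters (independent channels within the population)."""

    name: str
    fraction: float
    log_mean: dict[str, float]
    log_sd: dict[str, float]


@dataclass
class PanelSimConfig:
    """Configuration for one simulated flow-cytometry panel."""

    panel_name: str
    channels: list[str]
    populations: list[PopulationSpec]
    n_events: int
    isotype_log_mean: dict[str, float]
    isotype_log_sd: dict[str, float]
    condition: str = "glioma"
    compartment: str = "brain"
    day: int | None = 21
    n_isotype_events: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ValidationError("n_events must be at least 1")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"population fractions must sum to 1 (got {total!r})"
            )
        for pop in self.populations:
            if not (0.0 <= pop.fraction <= 1.0):
                raise ValidationError(f"fraction of {pop.name!r} outside [0, 1]")
            for ch in self.channels:
                if ch not in pop.log_mean or ch not in pop.log_sd:
                    raise ValidationError(
                        f"population {pop.name!r} lacks parameters for channel {ch!r}"
                    )
                if pop.log_sd[ch] < 0:
                    raise ValidationError("log-sd must be non-negative")
        for ch in self.channels:
            if ch not in self.isotype_log_mean or ch not in self.isotype_log_sd:
                raise ValidationError(f"isotype parameters missing for channel {ch!r}")


def generate_event_panel(
    config: PanelSimConfig,
) -> tuple[EventTable, EventTable, dict]:
    """Draw a stained event table, its isotype-control table and the planted
    ground truth.

    Stained events are a log-normal mixture over ``config.populations``;
    component counts are multinomial in the configured fractions and event
    rows are shuffled so population membership is not recoverable from row
    order.  The isotype table is drawn from the isotype distribution alone.
    Identical config + seed gives bit-identical output.
    """
    config.validate()
    rng = child_rng(config.seed, STREAM_STAINED)
    counts = rng.multinomial(config.n_events, [p.fraction for p in config.populations])
    blocks = []
    for pop, n in zip(config.populations, counts):
        cols = {
            ch: np.exp(rng.normal(pop.log_mean[ch], pop.log_sd[ch], size=n))
            if pop.log_sd[ch] > 0
            else np.full(n, math.exp(pop.log_mean[ch]))
            for ch in config.channels
        }
        blocks.append(pd.DataFrame(cols))
    data = pd.concat(blocks, ignore_index=True)
    data = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
    data.index.name = "event_id"

    iso_rng = child_rng(config.seed, STREAM_ISOTYPE)
    iso = pd.DataFrame(
        {
            ch: np.exp(
                iso_rng.normal(
                    config.isotype_log_mean[ch],
                    config.isotype_log_sd[ch],
                    size=config.n_isotype_events,
                )
            )
            for ch in config.channels
        }
    )
    iso.index.name = "event_id"

    meta = dict(
        panel=config.panel_name,
        condition=config.condition,
        compartment=config.compartment,
        day=config.day,
    )
    stained = EventTable(data, stain="antibody", **meta)
    isotype = EventTable(iso, stain="isotype", **meta)
    truth = {
        "panel": config.panel_name,
        "condition": config.condition,
        "compartment": config.compartment,
        "day": config.day,
        "n_events": config.n_events,
        "seed": config.seed,
        "fractions": {p.name: p.fraction for p in config.populations},
    }
    return stained, isotype, truth


def _negative_levels(channels) -> tuple[dict, dict]:
    return (
        {ch: NEGATIVE_LOG_MEAN for ch in channels},
        {ch: NEGATIVE_LOG_SD for ch in channels},
    )


def _isotype_levels(channels) -> tuple[dict, dict]:
    return (
        {ch: NEGATIVE_LOG_MEAN + ISOTYPE_LOG_OFFSET for ch in channels},
        {ch: ISOTYPE_LOG_SD for ch in channels},
    )


def _population(name, fraction, channels, high, cd45_level=None):
    """Build a PopulationSpec positive on ``high`` channels, negative elsewhere."""
    log_mean, log_sd = _negative_levels(channels)
    for ch in high:
        log_mean[ch] = POSITIVE_LOG_MEAN
        log_sd[ch] = POSITIVE_LOG_SD
    if cd45_level is not None:
        log_mean["CD45"] = cd45_level
        log_sd["CD45"] = CD45_LOG_SD
    return PopulationSpec(name, fraction, log_mean, log_sd)


# -- default panel factories (fractions are the emulated study's percentages)

#: myeloid-panel population fractions by condition (day 21 for glioma)
MYELOID_FRACTIONS = {
    "glioma": {"microglia": 0.28, "macrophage": 0.04, "leukocyte": 0.20},
    "sham": {"microglia": 0.13, "macrophage": 0.0, "leukocyte": 0.0},
    "naive": {"microglia": 0.13, "macrophage": 0.0, "leukocyte": 0.0},
}

#: single-marker T-cell fractions (brain); sham values are not printed by the
#: emulated study and are modest defaults consistent with its directionality
TCELL_FRACTIONS = {
    "glioma": {"FOXP3": 0.082, "CD4": 0.028, "CD8a": 0.020},
    "sham": {"FOXP3": 0.020, "CD4": 0.010, "CD8a": 0.030},
}

#: CD11b+Gr1+ double-positive fractions by (compartment, condition)
MDSC_FRACTIONS = {
    ("brain", "glioma"): 0.0399,
    ("brain", "sham"): 0.0105,
    ("blood", "glioma"): 0.063,
    ("blood", "sham"): 0.0211,
}

#: CD11b+Gr1- companion fraction (resident myeloid pool) by compartment
MDSC_CD11B_ONLY = {"brain": 0.28, "blood": 0.15}


def myeloid_panel_config(
    condition: str = "glioma",
    day: int = 21,
    n_events: int = 50_000,
    seed: int = 0,
    fractions: dict[str, float] | None = None,
) -> PanelSimConfig:
    """CD11b/CD45 panel: microglia (CD11b+CD45low), blood-derived macrophages
    (CD11b+CD45high), leukocytes (CD11b-CD45high) and a double-negative rest."""
    channels = ["CD11b", "CD45"]
    if fractions is None:
        fractions = MYELOID_FRACTIONS[condition]
    rest = 1.0 - sum(fractions.values())
    if rest < -1e-9:
        raise ValidationError("myeloid fractions exceed 1")
    pops = [
        _population("microglia", fractions["microglia"], channels, ["CD11b"],
                    cd45_level=CD45_LOW_LOG_MEAN),
        _population("macrophage", fractions["macrophage"], channels, ["CD11b"],
                    cd45_level=CD45_HIGH_LOG_MEAN),
        _population("leukocyte", fractions["leukocyte"], channels, [],
                    cd45_level=CD45_HIGH_LOG_MEAN),
        PopulationSpec("negative", rest, *_negative_levels(channels)),
    ]
    iso_mean, iso_sd = _isotype_levels(channels)
    return PanelSimConfig(
        panel_name="myeloid", channels=channels, populations=pops,
        n_events=n_events, isotype_log_mean=iso_mean, isotype_log_sd=iso_sd,
        condition=condition, compartment="brain", day=day, seed=seed,
    )


def tcell_panel_config(
    condition: str = "glioma",
    day: int = 21,
    n_events: int = 1_000_000,
    seed: int = 0,
    fractions: dict[str, float] | None = None,
) -> PanelSimConfig:
    """CD4/CD8a/FOXP3 panel with one single-positive population per marker.

    Populations are marker-exclusive (each positive on exactly one channel), a
    deliberate simplification: single-marker gating then recovers each planted
    fraction directly.  The default 10^6 events matches intracellular-FOXP3
    staining practice in the emulated study.
    """
    channels = ["CD4", "CD8a", "FOXP3"]
    if fractions is None:
        fractions = TCELL_FRACTIONS[condition]
    rest = 1.0 - sum(fractions.values())
    pops = [
        _population(f"{marker}_pos", frac, channels, [marker])
        for marker, frac in fractions.items()
    ]
    pops.append(PopulationSpec("negative", rest, *_negative_levels(channels)))
    iso_mean, iso_sd = _isotype_levels(channels)
    return PanelSimConfig(
        panel_name="tcell", channels=channels, populations=pops,
        n_events=n_events, isotype_log_mean=iso_mean, isotype_log_sd=iso_sd,
        condition=condition, compartment="brain", day=day, seed=seed,
    )


def mdsc_panel_config(
    condition: str = "glioma",
    compartment: str = "brain",
    day: int = 21,
    n_events: int = 100_000,
    seed: int = 0,
    dp_fraction: float | None = None,
) -> PanelSimConfig:
    """CD11b/Gr1 panel: CD11b+Gr1+ MDSCs, a CD11b+Gr1- myeloid pool, and a
    double-negative rest."""
    channels = ["CD11b", "Gr1"]
    if dp_fraction is None:
        dp_fraction = MDSC_FRACTIONS[(compartment, condition)]
    cd11b_only = MDSC_CD11B_ONLY[compartment]
    rest = 1.0 - dp_fraction - cd11b_only
    pops = [
        _population("mdsc", dp_fraction, channels, ["CD11b", "Gr1"]),
        _population("cd11b_only", cd11b_only, channels, ["CD11b"]),
        PopulationSpec("negative", rest, *_negative_levels(channels)),
    ]
    iso_mean, iso_sd = _isotype_levels(channels)
    return PanelSimConfig(
        panel_name="mdsc", channels=channels, populations=pops,
        n_events=n_events, isotype_log_mean=iso_mean, isotype_log_sd=iso_sd,
        condition=condition, compartment=compartment, day=day, seed=seed,
    )


# ---------------------------------------------------------------------------
# expression study simulation
# ---------------------------------------------------------------------------


@dataclass
class ExprSimConfig:
    """Two-group log2 expression simulation with planted effects.

    ``de_genes`` lists (gene, log2 effect) pairs added to tumor samples.
    ``planted_go_terms`` lists (term_id, gene tuple, direction) triples; every
    gene of a planted term receives ±``go_term_effect`` unless it already has
    an explicit entry in ``de_genes``.
    """

    n_genes: int = 1000
    n_control: int = 4
    n_tumor: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    planted_go_terms: list[tuple[str, tuple, str]] = field(default_factory=list)
    go_term_effect: float = 2.0
    genes: list[str] | None = None
    seed: int = 0

    def gene_universe(self) -> list[str]:
        if self.genes is not None:
            return list(self.genes)
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        universe = self.gene_universe()
        if len(set(universe)) != len(universe):
            seen: set = set()
            dupes = [g for g in universe if g in seen or seen.add(g)]
            raise ValidationError(f"duplicate gene identifier(s): {dupes[:5]}")
        if self.n_control < 2 or self.n_tumor < 2:
            raise ValidationError("need at least 2 samples per group (Welch "
                                  "requires a per-group variance)")
        uni = set(universe)
        for gene, _ in self.de_genes:
            if gene not in uni:
                raise ValidationError(f"planted DE gene {gene!r} not in universe")
        for term, genes, direction in self.planted_go_terms:
            if direction not in ("up", "down"):
                raise ValidationError(f"term {term!r} direction must be up|down")
            missing = set(genes) - uni
            if missing:
                raise ValidationError(
                    f"planted term {term!r} has genes outside universe: "
                    f"{sorted(missing)[:5]}"
                )

    def effect_map(self) -> dict[str, float]:
        """Combined per-gene planted log2 effect (explicit DE entries win)."""
        effects = {}
        for term, genes, direction in self.planted_go_terms:
            sign = 1.0 if direction == "up" else -1.0
            for g in genes:
                effects.setdefault(g, sign * self.go_term_effect)
        for gene, eff in self.de_genes:
            effects[gene] = eff
        return effects


def generate_expression_study(
    config: ExprSimConfig,
) -> tuple[ExpressionStudy, pd.DataFrame, list[dict]]:
    """Simulate a control-vs-tumor log2 expression matrix.

    Per-gene baselines are normal(``baseline_log2_mean``, ``baseline_log2_sd``)
    and shared across samples; i.i.d. normal noise of sd ``noise_sd`` is added
    per sample; tumor samples additionally receive the planted log2 effects.

    Returns the study, a DE ground-truth table (gene, log2_effect) listing
    every planted effect exactly once, and the GO ground truth (one record per
    planted term).
    """
    config.validate()
    rng = child_rng(config.seed, STREAM_EXPRESSION)
    genes = config.gene_universe()
    n_c, n_t = config.n_control, config.n_tumor
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=len(genes))
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), n_c + n_t)) \
        if config.noise_sd > 0 else np.zeros((len(genes), n_c + n_t))
    matrix = baseline[:, None] + noise
    effects = config.effect_map()
    if effects:
        idx = {g: i for i, g in enumerate(genes)}
        for gene, eff in effects.items():
            matrix[idx[gene], n_c:] += eff
    samples = [f"C{i+1}" for i in range(n_c)] + [f"T{i+1}" for i in range(n_t)]
    groups = pd.Series([CONTROL] * n_c + [TUMOR] * n_t, index=samples)
    study = ExpressionStudy(
        pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=samples),
        groups,
    )
    de_truth = pd.DataFrame(
        sorted(effects.items()), columns=["gene", "log2_effect"]
    )
    go_truth = [
        {"term": term, "genes": list(genes_), "direction": direction}
        for term, genes_, direction in config.planted_go_terms
    ]
    return study, de_truth, go_truth


def generate_go_annotation(
    universe,
    planted_terms=(),
    n_background_terms: int = 20,
    term_size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
) -> dict[str, set]:
    """Build a flat term→gene-set annotation: the planted terms plus random
    background terms drawn from the gene universe."""
    rng = child_rng(seed, STREAM_ANNOTATION)
    universe = list(universe)
    annotation: dict[str, set] = {
        term: set(genes) for term, genes, _ in planted_terms
    }
    lo, hi = term_size_range
    for i in range(n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        annotation[f"GO:BG{i:04d}"] = set(members.tolist())
    return annotation


# ---------------------------------------------------------------------------
# cross-species cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_SUBTYPES = ("Proneural", "Neural", "Classical", "Mesenchymal")


@dataclass
class CohortSimConfig:
    """Human GBM cohort + subtype signature + ortholog map + rat study.

    Human tumors of a subtype are shifted by ``centroid_shift`` log2 units on
    that subtype's signature genes; the rat tumors carry the target subtype's
    shifts attenuated by ``attenuation`` on genes retained in the ortholog
    map.  The default signature is 4 × 210 = 840 genes and the default
    retention 660/840 mirrors an Ensembl-style ortholog lookup.
    """

    subtypes: tuple = DEFAULT_SUBTYPES
    genes_per_subtype: int = 210
    centroid_shift: float = 1.5
    samples_per_subtype: int = 20
    n_normals: int = 10
    n_background_genes: int = 1160
    retention: float = 660 / 840
    target_subtype: str = "Mesenchymal"
    attenuation: float = 0.7
    n_rat_tumors: int = 3
    n_rat_controls: int = 4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.retention <= 1.0):
            raise ValidationError("retention fraction must be in (0, 1]")
        if self.target_subtype not in self.subtypes:
            raise ValidationError(
                f"target subtype {self.target_subtype!r} not among {self.subtypes}"
            )
        if not (0.0 < self.attenuation <= 1.0):
            raise ValidationError("attenuation must be in (0, 1]")
        if self.genes_per_subtype < 3:
            raise ValidationError("need at least 3 genes per subtype signature")


def generate_human_cohort(config: CohortSimConfig):
    """Simulate the full cross-species comparison input set.

    Returns ``(human_study, signature, ortholog_map, rat_study, truth)``
    where ``signature`` is a :class:`~gliomaprofiler.subtype_similarity.SignatureSet`,
    ``ortholog_map`` an :class:`~gliomaprofiler.subtype_similarity.OrthologMap`
    and ``truth`` records the planted subtype of every human tumor sample, the
    target subtype and the exact retained-orthologue count.
    """
    from .subtype_similarity import OrthologMap, SignatureSet

    config.validate()
    rng = child_rng(config.seed, STREAM_COHORT)

    n_sig = config.genes_per_subtype * len(config.subtypes)
    n_genes = n_sig + config.n_background_genes
    human_genes = [f"HS{i:05d}" for i in range(n_genes)]
    rat_genes = [f"Rn{i:05d}" for i in range(n_genes)]

    # disjoint signature blocks, assigned from a shuffled gene order so
    # signature membership is not recoverable from identifier rank
    order = rng.permutation(n_genes)
    signature_sets = {}
    for k, subtype in enumerate(config.subtypes):
        block = order[k * config.genes_per_subtype:(k + 1) * config.genes_per_subtype]
        signature_sets[subtype] = [human_genes[i] for i in sorted(block)]
    signature = SignatureSet(signature_sets)

    gene_pos = {g: i for i, g in enumerate(human_genes)}

    # human cohort: normals then per-subtype tumors
    n_tumors = config.samples_per_subtype * len(config.subtypes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=n_genes)
    human = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, config.n_normals + n_tumors)
    )
    samples, labels, planted = [], [], {}
    for i in range(config.n_normals):
        samples.append(f"N{i+1:02d}")
        labels.append(CONTROL)
    col = config.n_normals
    for subtype in config.subtypes:
        rows = [gene_pos[g] for g in signature_sets[subtype]]
        for j in range(config.samples_per_subtype):
            name = f"{subtype[:3].upper()}{j+1:02d}"
            samples.append(name)
            labels.append(TUMOR)
            planted[name] = subtype
            human[rows, col] += config.centroid_shift
            col += 1
    human_study = ExpressionStudy(
        pd.DataFrame(human, index=pd.Index(human_genes, name="gene"),
                     columns=samples),
        pd.Series(labels, index=samples),
        name="human_cohort",
    )

    # ortholog map: drop (1 - retention) of signature genes, keep the rest of
    # the universe; exact retained count by construction
    sig_genes = [g for s in config.subtypes for g in signature_sets[s]]
    n_keep = int(round(config.retention * len(sig_genes)))
    keep_idx = rng.choice(len(sig_genes), size=n_keep, replace=False)
    kept_sig = {sig_genes[i] for i in keep_idx}
    dropped = sorted(set(sig_genes) - kept_sig)
    pairs = [
        (rat_genes[gene_pos[g]], g)
        for g in human_genes
        if g in kept_sig or g not in set(sig_genes)
    ]
    for subtype in config.subtypes:
        n_mapped = sum(1 for g in signature_sets[subtype] if g in kept_sig)
        if n_mapped < 3:
            raise ValidationError(
                f"retention {config.retention} leaves only {n_mapped} mapped "
                f"genes for subtype {subtype!r}; need at least 3 for a "
                "meaningful correlation"
            )
    ortholog_map = OrthologMap(pairs)

    # rat study: independent species baseline; tumors carry the target
    # subtype's centroid, attenuated, through the mapped signature genes
    mapped_rat = [r for r, _ in pairs]
    rat_baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                              size=len(mapped_rat))
    n_rat = config.n_rat_controls + config.n_rat_tumors
    rat = rat_baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(mapped_rat), n_rat)
    )
    rat_pos = {r: i for i, r in enumerate(mapped_rat)}
    target_rows = [
        rat_pos[rat_genes[gene_pos[g]]]
        for g in signature_sets[config.target_subtype]
        if g in kept_sig
    ]
    rat[np.ix_(target_rows, range(config.n_rat_controls, n_rat))] += (
        config.attenuation * config.centroid_shift
    )
    rat_samples = [f"RC{i+1}" for i in range(config.n_rat_controls)] + [
        f"RT{i+1}" for i in range(config.n_rat_tumors)
    ]
    rat_groups = pd.Series(
        [CONTROL] * config.n_rat_controls + [TUMOR] * config.n_rat_tumors,
        index=rat_samples,
    )
    rat_study = ExpressionStudy(
        pd.DataFrame(rat, index=pd.Index(mapped_rat, name="gene"),
                     columns=rat_samples),
        rat_groups,
        name="rat_model",
    )

    truth = {
        "target_subtype": config.target_subtype,
        "n_signature_genes": len(sig_genes),
        "n_retained_orthologs": n_keep,
        "dropped_signature_genes": dropped,
        "subtype_assignments": planted,
        "seed": config.seed,
    }
    return human_study, signature, ortholog_map, rat_study, truth
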