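"""Canonical seeded experiments at the emulated study's conditions.

Each function regenerates its synthetic inputs at the documented default
configuration (the planted fractions, group sizes and noise levels the
simulators ship with), runs the corresponding analysis and returns the
measured quantities.  These are the entry points the reproduction script
and the recovery tests share, so both always measure the same procedure.
"""

from __future__ import annotations

import numpy as np

from .diffexpr import welch_de
from .gating import classify_mdsc, classify_myeloid, classify_tcell_panel, \
    derive_thresholds
from .subtype_similarity import assign_subtypes, fold_change_vector, \
    map_orthologs, similarity_ranking
from .synth import CohortSimConfig, ExprSimConfig, child_seed, \
    generate_event_panel, generate_expression_study, generate_human_cohort, \
    mdsc_panel_config, myeloid_panel_config, tcell_panel_config

N_MYELOID_EVENTS = 50_000
N_TCELL_EVENTS = 1_000_000
N_MDSC_EVENTS = 100_000


def myeloid_panel_percentages(seed: int, n_events: int = N_MYELOID_EVENTS) -> dict:
    """Gate a day-21 glioma myeloid panel and a sham panel.

    The CD45 low/high split is learned on the glioma panel (where both modes
    exist) and frozen for the sham panel, whose CD45-positive events are
    unimodal by construction.
    """
    glioma_cfg = myeloid_panel_config("glioma", n_events=n_events,
                                      seed=child_seed(seed, 10))
    stained, isotype, truth_g = generate_event_panel(glioma_cfg)
    th = derive_thresholds(stained, isotype)
    glioma = classify_myeloid(stained, th)

    sham_cfg = myeloid_panel_config("sham", n_events=n_events,
                                    seed=child_seed(seed, 11))
    sham_stained, sham_iso, truth_s = generate_event_panel(sham_cfg)
    sham_th = derive_thresholds(sham_stained, sham_iso,
                                cd45_split=th.cd45_split)
    sham = classify_myeloid(sham_stained, sham_th)
    return {
        "glioma_microglia_percent": glioma.percent("microglia"),
        "glioma_macrophage_percent": glioma.percent("macrophage"),
        "glioma_leukocyte_percent": glioma.percent("leukocyte"),
        "sham_microglia_percent": sham.percent("microglia"),
        "planted_glioma": truth_g["fractions"],
        "planted_sham": truth_s["fractions"],
        "n_events": n_events,
    }


def tcell_panel_percentages(seed: int, n_events: int = N_TCELL_EVENTS) -> dict:
    """Single-marker gating of the 10^6-event day-21 glioma T-cell panel."""
    cfg = tcell_panel_config("glioma", n_events=n_events,
                             seed=child_seed(seed, 12))
    stained, isotype, truth = generate_event_panel(cfg)
    th = derive_thresholds(stained, isotype)
    out = {"planted": truth["fractions"], "n_events": n_events}
    for marker in ("FOXP3", "CD4", "CD8a"):
        fr = classify_tcell_panel(stained, th, marker)
        out[f"{marker}_percent"] = fr.percent(f"{marker}_pos")
    return out


def mdsc_panel_percentages(seed: int, compartment: str,
                           n_events: int = N_MDSC_EVENTS) -> dict:
    """CD11b+Gr1+ recovery on a day-21 glioma MDSC panel."""
    cfg = mdsc_panel_config("glioma", compartment, n_events=n_events,
                            seed=child_seed(seed, 13 if compartment == "brain"
                                            else 14))
    stained, isotype, truth = generate_event_panel(cfg)
    fr = classify_mdsc(stained, derive_thresholds(stained, isotype))
    return {
        "mdsc_percent": fr.percent("mdsc"),
        "conditional_within_cd11b": fr.conditional.get(
            "gr1_pos_within_cd11b_pos"),
        "planted": truth["fractions"],
        "n_events": n_events,
    }


def de_null_calibration(seed: int, n_genes: int = 10_000,
                        alpha: float = 0.01) -> dict:
    """Type-I error of the Welch test on a no-effect simulation (4 vs 3)."""
    cfg = ExprSimConfig(n_genes=n_genes, n_control=4, n_tumor=3,
                        noise_sd=0.5, seed=child_seed(seed, 15))
    study, _, _ = generate_expression_study(cfg)
    res = welch_de(study, alpha)
    return {"m": res.m, "k": res.k, "alpha": alpha,
            "empirical_type1": res.k / res.m}


def de_planted_sensitivity(seed: int, n_genes: int = 2000, n_planted: int = 100,
                           effect: float = 2.0, alpha: float = 0.05) -> dict:
    """Recovery of planted ±``effect`` log2 effects (noise sd 0.5, 4 vs 3)."""
    genes = [f"G{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(child_seed(seed, 16))
    chosen = rng.choice(n_genes, size=n_planted, replace=False)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    de_genes = [(genes[i], float(s * effect)) for i, s in zip(chosen, signs)]
    cfg = ExprSimConfig(genes=genes, de_genes=de_genes, noise_sd=0.5,
                        n_control=4, n_tumor=3, seed=child_seed(seed, 17))
    study, truth, _ = generate_expression_study(cfg)
    res = welch_de(study, alpha)
    planted = truth["gene"].tolist()
    flagged = res.table.loc[planted, "significant"]
    false_pos = res.k - int(flagged.sum())
    return {
        "sensitivity": float(flagged.mean()),
        "k": res.k,
        "m": res.m,
        "fdr_hat": res.fdr_hat,
        "observed_fdr": false_pos / res.k if res.k else 0.0,
    }


def subtype_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Assignment accuracy and winner recovery over ``n_seeds`` cohorts at the
    default conditions (4 subtypes × 20 tumors, 10 normals, 840-gene
    signature with 660 retained orthologs, 3 rat replicates, Mesenchymal
    target, attenuation 0.7)."""
    correct, total, winners = 0, 0, 0
    for i in range(n_seeds):
        cfg = CohortSimConfig(seed=child_seed(seed, 1000 + i))
        human, sig, ortho, rat, truth = generate_human_cohort(cfg)
        assignment = assign_subtypes(human, sig)
        planted = truth["subtype_assignments"]
        correct += sum(assignment.assignments[s] == planted[s] for s in planted)
        total += len(planted)
        mapped = map_orthologs(list(rat.genes), ortho)
        sig_genes = set(sig.all_genes)
        mapped_sig = [(r, h) for r, h in mapped if h in sig_genes]
        res = similarity_ranking(
            fold_change_vector(rat, per_sample=True),
            fold_change_vector(human, per_sample=True),
            assignment, mapped_sig)
        winners += res.winner == truth["target_subtype"]
    return {
        "assignment_accuracy": correct / total,
        "winner_recovery_rate": winners / n_seeds,
        "n_seeds": n_seeds,
        "target": "Mesenchymal",
    }
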