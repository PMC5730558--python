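"""Threshold derivation, quadrant classification, kinetics and comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_event_table
from oracles import mann_whitney_exact_oracle
from gliomaprofiler.datatypes import ValidationError
from gliomaprofiler.gating import (
    GateThresholds,
    GatingError,
    classify_mdsc,
    classify_myeloid,
    classify_tcell_panel,
    compare_groups,
    derive_thresholds,
    kinetics_ratio,
)


def thresholds(**positive):
    split = positive.pop("cd45_split", None)
    return GateThresholds(positive=positive, cd45_split=split)


class TestDeriveThresholds:
    def test_constant_isotype_gives_that_constant(self):
        stained = make_event_table({"CD4": np.full(200, 50.0)})
        isotype = make_event_table({"CD4": np.full(200, 7.0)}, stain="isotype")
        th = derive_thresholds(stained, isotype)
        assert th.positive["CD4"] == pytest.approx(7.0)

    def test_lognormal_quantile_matches_closed_form(self, rng):
        mu, sigma, n = 3.2, 0.4, 100_000
        iso = make_event_table(
            {"CD4": np.exp(rng.normal(mu, sigma, n))}, stain="isotype")
        stained = make_event_table({"CD4": np.full(200, 100.0)})
        th = derive_thresholds(stained, iso, pos_quantile=0.99)
        analytic = math.exp(mu + sigma * stats.norm.ppf(0.99))
        assert abs(th.positive["CD4"] - analytic) / analytic < 0.02

    def test_cd45_split_lands_between_separated_modes(self, rng):
        low = rng.normal(4.0, 0.3, 5000)
        high = rng.normal(8.0, 0.3, 5000)
        cd45 = np.exp(np.concatenate([low, high]))
        stained = make_event_table(
            {"CD11b": np.full(10_000, 100.0), "CD45": cd45})
        iso = make_event_table(
            {"CD11b": np.exp(rng.normal(1.0, 0.2, 1000)),
             "CD45": np.exp(rng.normal(1.0, 0.2, 1000))}, stain="isotype")
        th = derive_thresholds(stained, iso)
        assert math.exp(4.0) < th.cd45_split < math.exp(8.0)
        log_split = math.log(th.cd45_split)
        assert np.mean(low < log_split) >= 0.99
        assert np.mean(high > log_split) >= 0.99

    def test_unimodal_cd45_raises_gating_error(self, rng):
        stained = make_event_table(
            {"CD45": np.exp(rng.normal(6.0, 0.3, 5000))})
        iso = make_event_table(
            {"CD45": np.exp(rng.normal(1.0, 0.2, 1000))}, stain="isotype")
        with pytest.raises(GatingError, match="manual"):
            derive_thresholds(stained, iso)

    def test_manual_split_override(self, rng):
        stained = make_event_table(
            {"CD45": np.exp(rng.normal(6.0, 0.3, 5000))})
        iso = make_event_table(
            {"CD45": np.exp(rng.normal(1.0, 0.2, 1000))}, stain="isotype")
        th = derive_thresholds(stained, iso, cd45_split=500.0)
        assert th.cd45_split == 500.0

    def test_tiny_isotype_rejected(self):
        stained = make_event_table({"CD4": np.full(200, 50.0)})
        isotype = make_event_table({"CD4": np.full(50, 7.0)}, stain="isotype")
        with pytest.raises(ValidationError, match="isotype"):
            derive_thresholds(stained, isotype)


class TestClassifyMyeloid:
    def exact_table(self):
        # 280 microglia-pattern, 40 macrophage, 200 leukocyte, 480 negative
        cd11b = np.r_[np.full(280, 100.0), np.full(40, 100.0),
                      np.full(200, 1.0), np.full(480, 1.0)]
        cd45 = np.r_[np.full(280, 50.0), np.full(40, 5000.0),
                     np.full(200, 5000.0), np.full(480, 1.0)]
        return make_event_table({"CD11b": cd11b, "CD45": cd45}, panel="myeloid")

    def test_counting_example(self):
        fr = classify_myeloid(self.exact_table(),
                              thresholds(CD11b=10.0, CD45=10.0, cd45_split=1000.0))
        assert fr.fractions == pytest.approx(
            {"microglia": 0.28, "macrophage": 0.04, "leukocyte": 0.20,
             "unclassified": 0.48})

    def test_all_below_thresholds_all_unclassified(self):
        events = make_event_table({"CD11b": np.full(10, 1.0),
                                   "CD45": np.full(10, 1.0)})
        fr = classify_myeloid(events,
                              thresholds(CD11b=10.0, CD45=10.0, cd45_split=100.0))
        assert fr.counts["unclassified"] == 10
        assert fr.fraction("microglia") == 0.0

    def test_threshold_equality_is_negative(self):
        events = make_event_table({"CD11b": np.array([10.0]),
                                   "CD45": np.array([10.0])})
        fr = classify_myeloid(events,
                              thresholds(CD11b=10.0, CD45=10.0, cd45_split=100.0))
        assert fr.counts["unclassified"] == 1

    def test_partition_property_on_random_events(self, rng):
        events = make_event_table(
            {"CD11b": np.exp(rng.normal(4, 2, 5000)),
             "CD45": np.exp(rng.normal(4, 2, 5000))})
        fr = classify_myeloid(events,
                              thresholds(CD11b=50.0, CD45=50.0, cd45_split=800.0))
        assert sum(fr.counts.values()) == 5000
        assert sum(fr.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_channel_schema_error(self):
        events = make_event_table({"CD11b": np.array([1.0])})
        with pytest.raises(ValidationError, match="CD45"):
            classify_myeloid(events,
                             thresholds(CD11b=1.0, CD45=1.0, cd45_split=10.0))

    def test_split_required(self):
        with pytest.raises(ValidationError, match="split"):
            classify_myeloid(self.exact_table(), thresholds(CD11b=1.0, CD45=1.0))


class TestClassifyTcell:
    def test_no_event_above_threshold_gives_zero(self):
        events = make_event_table({"CD4": np.full(100, 1.0)})
        fr = classify_tcell_panel(events, thresholds(CD4=10.0), "CD4")
        assert fr.fraction("CD4_pos") == 0.0

    def test_unknown_marker_lists_supported(self):
        events = make_event_table({"CD4": np.full(100, 1.0)})
        with pytest.raises(ValidationError, match="CD8a"):
            classify_tcell_panel(events, thresholds(CD4=10.0), "CD19")

    def test_raising_threshold_never_increases_fraction(self, rng):
        events = make_event_table({"FOXP3": np.exp(rng.normal(3, 1.5, 2000))})
        fractions = [
            classify_tcell_panel(events, thresholds(FOXP3=theta), "FOXP3")
            .fraction("FOXP3_pos")
            for theta in np.linspace(1.0, 500.0, 25)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestClassifyMdsc:
    def test_counting_example(self):
        # 100 events: 50 CD11b+, of which 10 also Gr1+
        cd11b = np.r_[np.full(50, 100.0), np.full(50, 1.0)]
        gr1 = np.r_[np.full(10, 100.0), np.full(90, 1.0)]
        events = make_event_table({"CD11b": cd11b, "Gr1": gr1})
        fr = classify_mdsc(events, thresholds(CD11b=10.0, Gr1=10.0))
        assert fr.fraction("mdsc") == pytest.approx(0.10)
        assert fr.conditional["gr1_pos_within_cd11b_pos"] == pytest.approx(0.20)

    def test_all_double_negative(self):
        events = make_event_table({"CD11b": np.full(20, 1.0),
                                   "Gr1": np.full(20, 1.0)})
        fr = classify_mdsc(events, thresholds(CD11b=10.0, Gr1=10.0))
        assert fr.fraction("mdsc") == 0.0
        assert "gr1_pos_within_cd11b_pos" in fr.undefined


class TestKinetics:
    def frac(self, **counts):
        from gliomaprofiler.gating import PopulationFractions
        total = sum(counts.values())
        return PopulationFractions(counts=counts, total=total)

    def test_identical_fractions_give_unit_ratios(self):
        a = self.frac(microglia=28, rest=72)
        res = kinetics_ratio(a, a, day=8)
        assert res.ratios["microglia"] == pytest.approx(1.0)

    def test_day21_microglia_ratio(self):
        glioma = self.frac(microglia=28, rest=72)
        sham = self.frac(microglia=13, rest=87)
        res = kinetics_ratio(glioma, sham, day=21)
        assert res.ratios["microglia"] == pytest.approx(28 / 13)

    def test_zero_sham_flagged_not_raised(self):
        glioma = self.frac(macrophage=4, rest=96)
        sham = self.frac(macrophage=0, rest=100)
        res = kinetics_ratio(glioma, sham)
        assert "macrophage" in res.undefined
        assert "macrophage" not in res.ratios


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.welch_t == pytest.approx(0.0)
        assert res.welch_p == pytest.approx(1.0)
        assert not res.significant

    def test_disjoint_small_groups_exact_p(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.mannwhitney_u in (0.0, 9.0)
        assert res.mannwhitney_p == pytest.approx(0.1)
        assert not res.significant  # 0.1 > 0.05

    def test_constant_equal_groups_not_significant(self):
        res = compare_groups([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.mannwhitney_p == pytest.approx(1.0)
        assert not res.significant

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 6)), int(r.integers(2, 6))
        pooled = r.choice(1000, size=n1 + n2, replace=False).astype(float)
        a, b = pooled[:n1], pooled[n1:]
        res = compare_groups(a, b)
        u_oracle, p_oracle = mann_whitney_exact_oracle(a, b)
        assert res.mannwhitney_p == pytest.approx(p_oracle, abs=1e-10)
        # scipy's U counts a>b pairs, matching the oracle's definition
        assert res.mannwhitney_u == pytest.approx(u_oracle)
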