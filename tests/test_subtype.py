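"""KS subtype assignment, ortholog mapping and similarity ranking."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from oracles import ks_uniform_oracle, spearman_oracle
from gliomaprofiler._stats import spearman
from gliomaprofiler.datatypes import ValidationError
from gliomaprofiler.subtype_similarity import (
    OrthologMap,
    SignatureSet,
    _ks_one_sample_uniform,
    assign_subtypes,
    fold_change_vector,
    map_orthologs,
    similarity_ranking,
)
from gliomaprofiler.synth import CohortSimConfig, generate_human_cohort


class TestKSStatistic:
    def test_hand_computed_ecdf_example(self):
        # 8 genes ranked, signature at top ranks 1..4 -> normalized {1/9..4/9}
        u = np.array([1, 2, 3, 4]) / 9.0
        d_plus, d, p = _ks_one_sample_uniform(u)
        assert d_plus == pytest.approx(5 / 9)
        assert d == pytest.approx(5 / 9)
        assert 0.0 < p < 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_ecdf_enumeration(self, seed):
        u = np.random.default_rng(seed).uniform(size=25)
        d_plus, d, _ = _ks_one_sample_uniform(u)
        o_plus, _, o_max = ks_uniform_oracle(u)
        assert d_plus == pytest.approx(o_plus, abs=1e-12)
        assert d == pytest.approx(o_max, abs=1e-12)

    def test_agrees_with_scipy_kstest(self, rng):
        u = rng.uniform(size=40)
        from scipy import stats
        _, d, p = _ks_one_sample_uniform(u)
        ref = stats.kstest(u, "uniform")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSignatureAndOrthologs:
    def test_overlapping_signature_rejected(self):
        with pytest.raises(ValidationError, match="shared"):
            SignatureSet({"A": ["g1", "g2", "g3"], "B": ["g3", "g4", "g5"]})

    def test_tiny_signature_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 3"):
            SignatureSet({"A": ["g1", "g2"]})

    def test_identity_map_maps_everything(self):
        m = OrthologMap([(f"r{i}", f"h{i}") for i in range(5)])
        pairs = map_orthologs([f"r{i}" for i in range(5)], m)
        assert len(pairs) == 5

    def test_one_to_many_pairs_dropped(self):
        m = OrthologMap([("r1", "h1"), ("r1", "h2"), ("r2", "h3"),
                         ("r3", "h3"), ("r4", "h4")])
        assert m.n_dropped_ambiguous == 4
        assert m.rat_to_human == {"r4": "h4"}

    def test_empty_intersection_raises(self):
        m = OrthologMap([("r1", "h1")])
        with pytest.raises(ValidationError, match="orthologue"):
            map_orthologs(["zz"], m)


class TestAssignment:
    def test_extreme_shift_assigns_that_subtype(self, rng):
        # subtype A genes occupy the top |A| expression ranks in sample T1
        genes = [f"g{i}" for i in range(40)]
        sig = SignatureSet({"A": genes[:5], "B": genes[5:10]})
        col = np.arange(40, 0, -1, dtype=float)  # g0 highest
        matrix = np.column_stack([rng.normal(8, 1, 40), col])
        study = make_study(matrix, genes, 1, 1)
        res = assign_subtypes(study, sig)
        assert res.assignments["T1"] == "A"
        table = res.ks_table.set_index(["sample", "subtype"])
        assert (table.loc[("T1", "A"), "D_up"]
                > table.loc[("T1", "B"), "D_up"])

    def test_every_tumor_sample_assigned_exactly_once(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sig = SignatureSet({"A": genes[:4], "B": genes[4:8]})
        study = make_study(rng.normal(8, 1, (30, 6)), genes, 2, 4)
        res = assign_subtypes(study, sig)
        assert sorted(res.assignments) == ["T1", "T2", "T3", "T4"]
        assert set(res.ks_table["subtype"]) == {"A", "B"}

    def test_signature_absent_from_matrix_rejected(self, rng):
        sig = SignatureSet({"A": ["x1", "x2", "x3"]})
        study = make_study(rng.normal(8, 1, (5, 4)),
                           [f"g{i}" for i in range(5)], 2, 2)
        with pytest.raises(ValidationError, match="present"):
            assign_subtypes(study, sig)


class TestFoldChange:
    def test_tumor_equal_to_normal_mean_gives_zero(self):
        study = make_study(np.array([[5.0, 7.0, 6.0]]), ["g"], 2, 1)
        fc = fold_change_vector(study)
        assert fc.loc["g", "log2fc"] == pytest.approx(0.0)

    def test_arithmetic_example(self):
        study = make_study(np.array([[6.0, 6.0, 8.0]]), ["g"], 2, 1)
        assert fold_change_vector(study).loc["g", "log2fc"] == pytest.approx(2.0)

    def test_per_sample_vectors_average_to_group_vector(self, rng):
        study = make_study(rng.normal(8, 1, (20, 7)),
                           [f"g{i}" for i in range(20)], 4, 3)
        per_sample = fold_change_vector(study, per_sample=True)
        group = fold_change_vector(study, per_sample=False)
        assert np.allclose(per_sample.mean(axis=1), group["log2fc"])

    def test_no_normals_is_an_error(self):
        study = make_study(np.ones((2, 2)), ["a", "b"], 0, 2)
        with pytest.raises(ValidationError, match="control"):
            fold_change_vector(study)


class TestSpearman:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rank_then_pearson_with_ties(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 30))
        x = r.integers(0, 8, size=n).astype(float)  # many ties
        y = x * r.normal(1, 0.5, size=n) + r.integers(0, 3, size=n)
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestSimilarityRanking:
    def build(self, rng, n_genes=30):
        genes = [f"h{i}" for i in range(n_genes)]
        rgenes = [f"r{i}" for i in range(n_genes)]
        pairs = list(zip(rgenes, genes))
        human_fcs = pd.DataFrame(
            rng.normal(0, 1, (n_genes, 4)), index=genes,
            columns=["s1", "s2", "s3", "s4"])
        from gliomaprofiler.subtype_similarity import SubtypeAssignment
        assignment = SubtypeAssignment(
            assignments={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
            ks_table=pd.DataFrame())
        return genes, rgenes, pairs, human_fcs, assignment

    def test_rat_equal_to_reference_wins_with_rho_one(self, rng):
        genes, rgenes, pairs, human_fcs, assignment = self.build(rng)
        ref_a = human_fcs[["s1", "s2"]].mean(axis=1)
        rat = pd.DataFrame({"r1": ref_a.to_numpy()}, index=rgenes)
        res = similarity_ranking(rat, human_fcs, assignment, pairs)
        assert res.winner == "A"
        assert res.mean_rho["A"] == pytest.approx(1.0)

    def test_monotone_transform_still_perfect(self, rng):
        genes, rgenes, pairs, human_fcs, assignment = self.build(rng)
        ref_a = human_fcs[["s1", "s2"]].mean(axis=1).to_numpy()
        rat = pd.DataFrame({"r1": np.exp(ref_a) + 5}, index=rgenes)
        res = similarity_ranking(rat, human_fcs, assignment, pairs)
        assert res.mean_rho["A"] == pytest.approx(1.0)

    def test_winner_invariant_to_input_order(self, rng):
        genes, rgenes, pairs, human_fcs, assignment = self.build(rng)
        rat = pd.DataFrame(rng.normal(0, 1, (len(rgenes), 3)),
                           index=rgenes, columns=["r1", "r2", "r3"])
        res1 = similarity_ranking(rat, human_fcs, assignment, pairs)
        perm = rng.permutation(len(pairs))
        res2 = similarity_ranking(rat, human_fcs, assignment,
                                  [pairs[i] for i in perm])
        assert res1.winner == res2.winner
        for s in res1.mean_rho:
            assert res1.mean_rho[s] == pytest.approx(res2.mean_rho[s], abs=1e-12)

    def test_subtype_without_samples_excluded(self, rng):
        genes, rgenes, pairs, human_fcs, assignment = self.build(rng)
        assignment.assignments = {"s1": "A", "s2": "A", "s3": "A", "s4": "A"}
        rat = pd.DataFrame(rng.normal(0, 1, (len(rgenes), 3)),
                           index=rgenes, columns=["r1", "r2", "r3"])
        res = similarity_ranking(rat, human_fcs, assignment, pairs)
        assert list(res.rho) == ["A"]

    def test_small_replicate_count_warns(self, rng):
        genes, rgenes, pairs, human_fcs, assignment = self.build(rng)
        rat = pd.DataFrame(rng.normal(0, 1, (len(rgenes), 3)),
                           index=rgenes, columns=["r1", "r2", "r3"])
        res = similarity_ranking(rat, human_fcs, assignment, pairs)
        assert any("0.1" in w for w in res.warnings)
        assert all(p >= 0.1 for p in res.pairwise_p.values())


class TestPlantedCohortRecovery:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_assignment_accuracy_and_winner(self, seed):
        cfg = CohortSimConfig(seed=seed)
        human, sig, ortho, rat, truth = generate_human_cohort(cfg)
        assignment = assign_subtypes(human, sig)
        planted = truth["subtype_assignments"]
        accuracy = np.mean([assignment.assignments[s] == planted[s]
                            for s in planted])
        assert accuracy >= 0.95
        mapped = map_orthologs(list(rat.genes), ortho)
        sig_genes = set(sig.all_genes)
        mapped_sig = [(r, h) for r, h in mapped if h in sig_genes]
        assert len(mapped_sig) == truth["n_retained_orthologs"]
        res = similarity_ranking(
            fold_change_vector(rat, per_sample=True),
            fold_change_vector(human, per_sample=True),
            assignment, mapped_sig)
        assert res.winner == truth["target_subtype"]
        assert res.ranking[0] == res.winner
        assert all(-1.0 <= r <= 1.0
                   for rhos in res.rho.values() for r in rhos)
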