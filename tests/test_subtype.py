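import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metabosubtype.datatypes import ClinicalTable, ExpressionMatrix
from metabosubtype.simulate import SubtypeSimConfig, simulate_expression_cohort
from metabosubtype.subtype import (
    ConsensusParams,
    MetabolicSubtyper,
    assign_subtypes,
    consensus_cluster,
    pathway_score,
    select_coexpressed_group,
    specific_molecules,
    subset_pathway_genes,
    subtype_group_tests,
    subtype_survival,
)


def _two_block_matrix(seed=7, n_samples=60, rho=0.9):
    """Two clean gene blocks (within r ~ rho, between ~ 0)."""
    rng = np.random.default_rng(seed)
    blocks = []
    ids = []
    for b in range(2):
        f = rng.standard_normal(n_samples)
        x = np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * rng.standard_normal((8, n_samples))
        blocks.append(x)
        ids += [f"b{b}_g{i}" for i in range(8)]
    return pd.DataFrame(np.vstack(blocks), index=ids,
                        columns=[f"s{i}" for i in range(n_samples)])


class TestSubset:
    def test_full_set_present(self, expression_cohort, gene_sets):
        _, expr, _, _ = expression_cohort
        sub, missing = subset_pathway_genes(expr, gene_sets["AAG_METABOLISM"])
        assert sub.shape[0] == len(gene_sets["AAG_METABOLISM"])
        assert missing == []

    def test_partially_absent_reported(self, expression_cohort):
        _, expr, _, _ = expression_cohort
        genes = expr.feature_ids[:3] + ["ghost1", "ghost2"]
        sub, missing = subset_pathway_genes(expr, genes)
        assert sub.shape[0] == 3
        assert missing == ["ghost1", "ghost2"]

    def test_empty_intersection_rejected(self, expression_cohort):
        _, expr, _, _ = expression_cohort
        with pytest.raises(ValueError, match="overlap"):
            subset_pathway_genes(expr, ["ghost"])


class TestConsensusCluster:
    def test_two_planted_blocks_sharp_consensus(self):
        sub = _two_block_matrix()
        res = consensus_cluster(sub, ConsensusParams(k=2, reps=100, seed=7))
        m = res.consensus.to_numpy()
        within = np.concatenate([
            m[:8, :8][np.triu_indices(8, 1)], m[8:, 8:][np.triu_indices(8, 1)]
        ])
        between = m[:8, 8:].ravel()
        assert within.mean() >= 0.9
        assert between.mean() <= 0.1
        truth = [0] * 8 + [1] * 8
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equal_items_gives_singletons(self):
        sub = _two_block_matrix()[:6]
        res = consensus_cluster(sub, ConsensusParams(k=6, reps=20, seed=1))
        assert res.labels.nunique() == 6

    def test_seed_determinism(self):
        sub = _two_block_matrix()
        a = consensus_cluster(sub, ConsensusParams(k=2, reps=30, seed=5))
        b = consensus_cluster(sub, ConsensusParams(k=2, reps=30, seed=5))
        assert a.consensus.equals(b.consensus)
        assert a.labels.equals(b.labels)

    def test_item_order_invariance(self):
        sub = _two_block_matrix()
        a = consensus_cluster(sub, ConsensusParams(k=2, reps=30, seed=5))
        perm = np.random.default_rng(0).permutation(len(sub))
        b = consensus_cluster(sub.iloc[perm], ConsensusParams(k=2, reps=30, seed=5))
        common = sub.index
        assert np.allclose(a.consensus.loc[common, common], b.consensus.loc[common, common])

    def test_consensus_matrix_invariants(self):
        sub = _two_block_matrix()
        res = consensus_cluster(sub, ConsensusParams(k=3, reps=25, seed=2))
        m = res.consensus.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_k_exceeding_items_rejected(self):
        sub = _two_block_matrix()[:4]
        with pytest.raises(ValueError):
            consensus_cluster(sub, ConsensusParams(k=5))


class TestSelectGroup:
    def test_core_beats_decoys(self, expression_cohort, gene_sets):
        _, expr, _, truth = expression_cohort
        sub, _ = subset_pathway_genes(expr, gene_sets["AAG_METABOLISM"])
        res = consensus_cluster(sub, ConsensusParams(seed=7))
        genes = select_coexpressed_group(sub, res.labels)
        assert sorted(genes) == sorted(truth.true_cores["AAG"])

    def test_negative_correlation_cluster_not_chosen(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(50)
        pos = np.vstack([f + rng.standard_normal(50) * 0.3 for _ in range(3)])
        anti = np.vstack([f, -f, f + rng.standard_normal(50) * 0.1])
        sub = pd.DataFrame(np.vstack([pos, anti]),
                           index=[f"g{i}" for i in range(6)])
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=sub.index)
        chosen = select_coexpressed_group(sub, labels)
        assert chosen == ["g0", "g1", "g2"]

    def test_all_singletons_rejected(self):
        sub = _two_block_matrix()[:3]
        labels = pd.Series([1, 2, 3], index=sub.index)
        with pytest.raises(ValueError):
            select_coexpressed_group(sub, labels)


class TestScoresAndQuadrants:
    def test_sample_at_gene_means_scores_zero(self):
        # last sample sits exactly at every gene's mean: rows [a, 2m-a, m]
        x = np.array([[1.0, 5.0, 3.0], [10.0, 30.0, 20.0], [-4.0, 2.0, -1.0]])
        df = pd.DataFrame(x, index=["g1", "g2", "g3"])
        score = pathway_score(df, ["g1", "g2", "g3"])
        assert score.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_median_of_z_values(self):
        # three genes whose z-scores for the last sample are 1, -1 and 0.5
        base = np.array([
            [0.0, 2.0, 1.0, 1.0 + np.sqrt(2.0 / 3.0)],
            [0.0, 2.0, 1.0, 1.0 - np.sqrt(2.0 / 3.0)],
            [0.0, 2.0, 1.0, 1.0 + 0.5 * np.sqrt(2.0 / 3.0)],
        ])
        df = pd.DataFrame(base, index=["a", "b", "c"])
        score = pathway_score(df, ["a", "b", "c"])
        z_last = (base[:, 3] - base.mean(axis=1)) / base.std(axis=1, ddof=1)
        assert score.iloc[3] == pytest.approx(np.median(z_last))

    def test_gene_shift_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((4, 20)), index=list("abcd"))
        s1 = pathway_score(df, list("abcd"))
        shifted = df.copy()
        shifted.loc["b"] += 13.5
        s2 = pathway_score(shifted, list("abcd"))
        assert np.allclose(s1, s2)

    def test_single_sample_rejected(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            pathway_score(df, ["g"])

    @pytest.mark.parametrize(
        "aag,gg,expected",
        [
            (0.0, 0.0, "quiescent"),
            (0.3, 0.0, "AAG"),
            (0.0, 0.3, "GG"),
            (0.3, 0.3, "mixed"),
            (-0.1, -0.1, "quiescent"),
        ],
    )
    def test_quadrant_rule_boundaries(self, aag, gg, expected):
        out = assign_subtypes(pd.Series({"s": aag}), pd.Series({"s": gg}))
        assert out.loc["s", "label"] == expected

    def test_labels_partition_samples(self, expression_cohort, gene_sets):
        _, expr, _, _ = expression_cohort
        model = MetabolicSubtyper(expr, gene_sets, params=ConsensusParams(seed=7))
        res = model.fit()
        assert res.subtype_counts().sum() == len(expr.sample_ids)

    def test_missing_score_excluded_with_warning(self):
        aag = pd.Series({"s1": 0.5, "s2": np.nan})
        gg = pd.Series({"s1": -0.5, "s2": 0.1})
        with pytest.warns(UserWarning):
            out = assign_subtypes(aag, gg)
        assert list(out.index) == ["s1"]


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_subtypes(self, expression_cohort, gene_sets):
        """Full subset -> consensus -> select -> score -> assign chain."""
        _, expr, _, truth = expression_cohort
        model = MetabolicSubtyper(expr, gene_sets, params=ConsensusParams(seed=7))
        res = model.fit()
        for pw in ("AAG", "GG"):
            assert sorted(res.selected_genes[pw]) == sorted(truth.true_cores[pw])
        truth_labels = pd.Series(truth.true_subtype)[res.labels.index]
        assert adjusted_rand_score(truth_labels, res.labels) >= 0.9


class TestSpecificMolecules:
    def _labelled_features(self, n_marker_shift=0.0, seed=47, n_per=50, n_feat=60):
        rng = np.random.default_rng(seed)
        labels = pd.Series(
            np.repeat(["quiescent", "AAG", "GG", "mixed"], n_per),
            index=[f"s{i}" for i in range(4 * n_per)],
        )
        x = rng.standard_normal((n_feat, 4 * n_per))
        if n_marker_shift:
            x[0, labels.to_numpy() == "GG"] += n_marker_shift
            x[1, np.isin(labels.to_numpy(), ["GG", "AAG"])] += n_marker_shift
        return pd.DataFrame(x, index=[f"f{i}" for i in range(n_feat)],
                            columns=labels.index), labels

    def test_null_yields_almost_nothing(self):
        total = 0
        for rep in range(5):
            features, labels = self._labelled_features(seed=47 + rep)
            out = specific_molecules(features, labels)
            total += sum(len(v) for v in out["specific"].values())
        assert total <= 0.01 * 5 * 60 * 4 + 1

    def test_planted_marker_recovered_in_its_subtype_only(self):
        features, labels = self._labelled_features(n_marker_shift=2.0)
        out = specific_molecules(features, labels)
        assert "f0" in out["specific"]["GG"]
        for other in ("quiescent", "AAG", "mixed"):
            assert "f0" not in out["specific"][other]

    def test_marker_in_two_subtypes_specific_to_neither(self):
        features, labels = self._labelled_features(n_marker_shift=2.0)
        out = specific_molecules(features, labels)
        for s in out["specific"]:
            assert "f1" not in out["specific"][s]

    def test_tiny_subtype_excluded_with_warning(self):
        features, labels = self._labelled_features(n_marker_shift=2.0)
        labels.iloc[:-1] = labels.iloc[:-1]
        small = labels.copy()
        small[small.index[:199]] = "quiescent"  # leaves one AAG sample
        small[small.index[199]] = "AAG"
        with pytest.warns(UserWarning, match="excluded"):
            specific_molecules(features.iloc[:5], small)


class TestGroupTests:
    def test_constant_feature_not_retained(self):
        labels = pd.Series(["quiescent", "AAG", "GG", "mixed"] * 10,
                           index=[f"s{i}" for i in range(40)])
        x = pd.DataFrame(np.ones((1, 40)), index=["flat"], columns=labels.index)
        full, retained = subtype_group_tests(x, labels)
        assert full.loc["flat", "p"] == 1.0
        assert "flat" not in retained.index

    def test_erbb2_like_gene_retained_lowest_in_gg(self, expression_cohort, gene_sets):
        _, expr, _, truth = expression_cohort
        labels = pd.Series(truth.true_subtype)
        rng = np.random.default_rng(7)
        erbb2 = pd.Series(rng.standard_normal(len(labels)), index=labels.index)
        erbb2[labels == "GG"] -= 2.0
        x = pd.DataFrame([erbb2], index=["ERBB2"])
        full, retained = subtype_group_tests(x, labels)
        assert "ERBB2" in retained.index
        medians = {lev: erbb2[labels == lev].median() for lev in labels.unique()}
        assert min(medians, key=medians.get) == "GG"

    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(49)
        labels = pd.Series(np.repeat(["quiescent", "AAG", "GG", "mixed"], 25),
                           index=[f"s{i}" for i in range(100)])
        x = pd.DataFrame(rng.standard_normal((1000, 100)), columns=labels.index)
        full, retained = subtype_group_tests(x, labels)
        frac = len(retained) / len(full)
        assert abs(frac - 0.05) <= 0.02


class TestSurvival:
    def _clinical(self, times, events, ids):
        return ClinicalTable(pd.DataFrame(
            {"sample_id": ids, "os_time": times, "os_event": events,
             "dss_time": times, "dss_event": events}
        ))

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(0)
        t = np.tile(rng.exponential(100, 40), 2)
        ids = [f"s{i}" for i in range(80)]
        clin = self._clinical(t, np.ones(80, dtype=int), ids)
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=ids)
        res = subtype_survival(clin, labels, "OS")
        assert res["test"].p > 0.9

    def test_planted_hazards_detected_and_ordered(self, expression_cohort, gene_sets):
        _, expr, clin, truth = expression_cohort
        labels = pd.Series(truth.true_subtype)
        res = subtype_survival(clin, labels, "OS")
        assert res["test"].p < 0.01
        curves = res["curves"]
        t_med = np.median(clin.table["os_time"])
        surv = {lev: c.survival_at(t_med) for lev, c in curves.items()}
        assert min(surv, key=surv.get) == "GG"
        assert max(surv, key=surv.get) == "mixed"

    def test_missing_followup_excluded_exactly(self):
        ids = [f"s{i}" for i in range(6)]
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ids,
            "os_time": [5.0, 6.0, np.nan, 8.0, 9.0, 10.0],
            "os_event": [1, 1, 1, np.nan, 1, 0],
        }))
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=ids)
        res = subtype_survival(clin, labels, "OS")
        assert res["n"] == 4

    def test_fully_censored_group_keeps_df(self):
        ids = [f"s{i}" for i in range(60)]
        rng = np.random.default_rng(1)
        times = rng.exponential(50, 60)
        events = np.ones(60, dtype=int)
        events[:15] = 0  # first subtype fully censored
        clin = self._clinical(times, events, ids)
        labels = pd.Series(np.repeat(["w", "x", "y", "z"], 15), index=ids)
        res = subtype_survival(clin, labels, "OS")
        assert res["test"].df == 3

    def test_dss_endpoint_uses_dss_columns(self, expression_cohort):
        _, _, clin, truth = expression_cohort
        labels = pd.Series(truth.true_subtype)
        res = subtype_survival(clin, labels, "DSS")
        assert res["endpoint"] == "DSS"
        assert res["n"] == len(labels)


class TestCrosstab:
    def test_immune_subtype_crosstab_shape(self, expression_cohort, gene_sets):
        _, expr, clin, _ = expression_cohort
        model = MetabolicSubtyper(expr, gene_sets, clinical=clin,
                                  params=ConsensusParams(seed=7))
        res = model.fit()
        tab = res.crosstab("immune_subtype")
        assert tab.to_numpy().sum() == len(res.labels)
        assert set(tab.columns) <= {f"C{i}" for i in range(1, 7)}
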