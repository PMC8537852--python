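"""Discovery-stage statistics: fold changes, z-centering, moderated test,
BH adjustment, selection, shortlist, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster.hierarchy import to_tree

from uroprot.discovery import (
    ModeratedTestParams,
    SelectionCriteria,
    adjust_bh,
    center_fold_changes,
    cluster_samples,
    compute_log2fc,
    differential_abundance,
    filter_quantified,
    moderated_t_test,
    pca_scores,
    select_regulated,
    shortlist_candidates,
)
from uroprot.synthetic import (
    CohortConfig,
    generate_discovery_cohort,
    make_sample_table,
)


class TestFilterQuantified:
    def test_fully_observed_protein_retained(self, small_matrix, small_samples):
        out = filter_quantified(small_matrix, small_samples, 0.5)
        assert list(out.index) == list(small_matrix.index)

    def test_single_observation_per_group_dropped(self, small_matrix, small_samples):
        m = small_matrix.copy()
        m.iloc[0, 1:4] = np.nan  # one case value left
        m.iloc[0, 5:] = np.nan  # one control value left
        out = filter_quantified(m, small_samples, 0.5)
        assert m.index[0] not in out.index

    def test_matches_brute_force_scan(self, small_samples):
        rng = np.random.default_rng(0)
        values = 2.0 ** rng.normal(18, 2, size=(10, 8))
        values[rng.random(values.shape) < 0.35] = np.nan
        m = pd.DataFrame(
            values, index=[f"P{i}" for i in range(10)],
            columns=small_samples["sample_id"].tolist(),
        )
        min_fraction = 0.5
        case = small_samples[small_samples.group == "case"]["sample_id"]
        ctrl = small_samples[small_samples.group == "control"]["sample_id"]
        expected = []
        for prot in m.index:
            nc = m.loc[prot, case].notna().sum()
            nn = m.loc[prot, ctrl].notna().sum()
            frac = nc >= min_fraction * len(case) or nn >= min_fraction * len(ctrl)
            if frac and nc >= 2 and nn >= 2:
                expected.append(prot)
        out = filter_quantified(m, small_samples, min_fraction)
        assert list(out.index) == expected


class TestLog2FoldChange:
    def test_exact_arithmetic(self):
        samples = make_sample_table(2, 2)
        m = pd.DataFrame(
            [[4.0, 4.0, 2.0, 2.0], [8.0, 8.0, 8.0, 8.0]],
            index=["A", "B"], columns=samples["sample_id"].tolist(),
        )
        fc = compute_log2fc(m, samples)
        assert fc.loc["A", "log2fc"] == pytest.approx(1.0)
        assert fc.loc["B", "log2fc"] == pytest.approx(0.0)

    def test_matches_mean_difference_oracle(self, small_matrix, small_samples):
        fc = compute_log2fc(small_matrix, small_samples)
        case = small_samples[small_samples.group == "case"]["sample_id"]
        ctrl = small_samples[small_samples.group == "control"]["sample_id"]
        for prot in small_matrix.index:
            expected = np.log2(small_matrix.loc[prot, case]).mean() - np.log2(
                small_matrix.loc[prot, ctrl]
            ).mean()
            assert fc.loc[prot, "log2fc"] == pytest.approx(expected, abs=1e-12)


class TestCenterFoldChanges:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(center_fold_changes([1, 2, 3]), [-1, 0, 1])

    def test_location_invariance_under_global_shift(self):
        rng = np.random.default_rng(1)
        fc = rng.normal(0, 1, 100)
        np.testing.assert_allclose(
            center_fold_changes(fc), center_fold_changes(fc + 3.7), atol=1e-10
        )

    def test_output_standardized(self):
        z = center_fold_changes(np.random.default_rng(2).normal(2, 3, 500))
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            center_fold_changes([5.0, 5.0, 5.0])


class TestBenjaminiHochberg:
    def test_hand_run_examples(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(adjust_bh([0.005, 0.1]), [0.01, 0.1])
        np.testing.assert_allclose(adjust_bh([0.42]), [0.42])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_and_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        q = adjust_bh(p)
        # brute-force step-up
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            expected[i] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        # monotone in p
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestModeratedTest:
    @pytest.fixture
    def random_matrix(self):
        samples = make_sample_table(12, 12)
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            2.0 ** rng.normal(20, 2, size=(100, 24)),
            index=[f"P{i}" for i in range(100)],
            columns=samples["sample_id"].tolist(),
        )
        return m, samples

    def test_d0_zero_equals_classical_pooled_t(self, random_matrix):
        m, samples = random_matrix
        res = moderated_t_test(m, samples, ModeratedTestParams(d0=0.0, s0_sq=1.0))
        case = samples[samples.group == "case"]["sample_id"]
        ctrl = samples[samples.group == "control"]["sample_id"]
        logm = np.log2(m)
        t_ref, p_ref = stats.ttest_ind(
            logm[case], logm[ctrl], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-8)
        np.testing.assert_allclose(res["p_raw"], p_ref, atol=1e-8)

    def test_d0_infinite_shrinks_all_variances_to_prior(self, random_matrix):
        m, samples = random_matrix
        res = moderated_t_test(m, samples, ModeratedTestParams(d0=np.inf, s0_sq=0.3))
        assert np.allclose(res["s2_post"], 0.3)
        assert np.isinf(res["df_total"]).all()

    def test_estimated_prior_shrinks_toward_pooled_scale(self, random_matrix):
        m, samples = random_matrix
        res = moderated_t_test(m, samples, "estimate")
        # posterior variances lie between the raw extremes
        assert res["s2_post"].min() >= res["s2"].min() - 1e-12
        assert res["s2_post"].max() <= res["s2"].max() + 1e-12


class TestSelection:
    def test_dual_criterion_with_strict_inequalities(self):
        records = pd.DataFrame(
            {
                "z": [2.5, 1.96, -2.2, 3.0, 0.1],
                "q": [0.01, 0.001, 0.04, 0.05, 0.001],
            },
            index=["up1", "edge_z", "down1", "edge_q", "null"],
        )
        up, down = select_regulated(records, SelectionCriteria(1.96, 0.05))
        assert up == ["up1"]
        assert down == ["down1"]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SelectionCriteria(z_abs_threshold=0.0)


class TestShortlist:
    @pytest.fixture
    def up_records(self):
        return pd.DataFrame(
            {"log2fc": [3.0, 2.0, 1.5]}, index=["A", "B", "C"]
        )

    def test_modified_and_missed_cleavage_peptides_excluded(self, up_records):
        ev = pd.DataFrame(
            {
                "protein_id": ["A"] * 3 + ["B"] * 2 + ["C"] * 2,
                "peptide_sequence": ["a1", "a2", "a3", "b1", "b2", "c1", "c2"],
                "has_oxidized_met": [False, False, True, False, False, False, False],
                "missed_cleavages": [0, 0, 0, 0, 1, 0, 0],
                "total_intensity": [10.0, 20.0, 99.0, 5.0, 50.0, 7.0, 8.0],
            }
        )
        out = shortlist_candidates(up_records, ev, n_select=3)
        # B has only one eligible peptide -> dropped entirely
        assert list(out["protein_id"]) == ["A", "C"]
        row_a = out[out.protein_id == "A"].iloc[0]
        assert {row_a["peptide_1"], row_a["peptide_2"]} == {"a1", "a2"}
        assert row_a["peptide_1"] == "a2"  # higher intensity first

    def test_ranking_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        prots = [f"P{i}" for i in range(12)]
        up = pd.DataFrame({"log2fc": rng.normal(2, 0.5, 12)}, index=prots)
        ev = pd.DataFrame(
            {
                "protein_id": np.repeat(prots, 3),
                "peptide_sequence": [f"pep{i}" for i in range(36)],
                "has_oxidized_met": False,
                "missed_cleavages": 0,
                "total_intensity": rng.uniform(1, 100, 36),
            }
        )
        out = shortlist_candidates(up, ev, n_select=5)
        totals = ev.groupby("protein_id")["total_intensity"].sum()
        expected = sorted(
            prots, key=lambda p: (up.loc[p, "log2fc"], totals[p]), reverse=True
        )[:5]
        assert list(out["protein_id"]) == expected
        assert list(out["rank"]) == [1, 2, 3, 4, 5]


class TestPca:
    def test_duplicated_sample_identical_coordinates(self, small_matrix, small_samples):
        m = small_matrix.copy()
        m["dup"] = m[m.columns[0]]
        scores, _ = pca_scores(m)
        np.testing.assert_allclose(
            scores.loc[m.columns[0]], scores.loc["dup"], atol=1e-8
        )

    def test_component_scores_orthogonal(self, small_matrix):
        scores, _ = pca_scores(small_matrix)
        g = scores.T @ scores
        off = g.to_numpy() - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8

    def test_planted_group_effect_separates_on_pc1(self):
        hits = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_case=8, n_control=8, n_proteins=150, n_de_up=30, n_de_down=0,
                de_log2fc_range=(2.0, 3.0), proteinuria_log2_mean=0.0,
                proteinuria_log2_sd=0.0, missing_midpoint_log2=-50.0, seed=seed,
            )
            matrix, samples, _ = generate_discovery_cohort(cfg)
            scores, _ = pca_scores(matrix)
            pc1 = scores["PC1"]
            case = samples[samples.group == "case"]["sample_id"]
            ctrl = samples[samples.group == "control"]["sample_id"]
            lo, hi = sorted([pc1[case].mean(), pc1[ctrl].mean()])
            sep = (pc1[case].max() < pc1[ctrl].min()) or (
                pc1[ctrl].max() < pc1[case].min()
            )
            hits += sep
        assert hits >= 19  # >= 95% of replicates

    def test_requires_three_samples(self):
        m = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            pca_scores(m)


class TestClustering:
    def test_identical_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            2.0 ** rng.normal(15, 1, size=(20, 4)), columns=["a", "b", "c", "d"]
        )
        m["b"] = m["a"]
        dendro = cluster_samples(m)
        Z = dendro.linkage_matrix
        assert Z[0, 3] == 2 and Z[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_heights_non_decreasing(self, small_matrix):
        Z = cluster_samples(small_matrix).linkage_matrix
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_four_point_example_matches_exhaustive_complete_linkage(self):
        # 1-d arrangement 0, 1, 5, 5.5 after centering; distances known
        m = pd.DataFrame(
            [[2.0**0, 2.0**1, 2.0**5, 2.0**5.5]], columns=list("abcd")
        )
        # pad with constant rows so centering leaves the geometry intact
        m = pd.concat([m, m * 0 + 1.0], ignore_index=True)
        dendro = cluster_samples(m)
        Z = dendro.linkage_matrix
        # closest pair: c,d (0.5); then a,b (1.0); final merge at complete
        # linkage distance max over pairs = 5.5
        assert {int(Z[0, 0]), int(Z[0, 1])} == {2, 3}
        assert Z[0, 2] == pytest.approx(0.5)
        assert {int(Z[1, 0]), int(Z[1, 1])} == {0, 1}
        assert Z[1, 2] == pytest.approx(1.0)
        assert Z[2, 2] == pytest.approx(5.5)

    def test_newick_export_contains_all_samples(self, small_matrix):
        import dendropy

        dendro = cluster_samples(small_matrix)
        tree = dendropy.Tree.get(
            data=dendro.to_newick(), schema="newick", preserve_underscores=True
        )
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == set(small_matrix.columns)


class TestDifferentialAbundance:
    def test_recovers_planted_effect(self):
        cfg = CohortConfig(
            n_proteins=300, n_de_up=10, n_de_down=0,
            de_log2fc_range=(2.5, 3.0), seed=13,
        )
        matrix, samples, truth = generate_discovery_cohort(cfg)
        rec = differential_abundance(matrix, samples)
        selected = set(rec.index[rec.direction == "up"])
        planted = set(truth.de_log2fc)
        assert len(selected & planted) >= 8

    def test_z_column_is_centered(self, small_matrix, small_samples):
        rec = differential_abundance(small_matrix, small_samples)
        assert rec["z"].mean() == pytest.approx(0.0, abs=1e-10)
        assert rec["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
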