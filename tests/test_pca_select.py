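"""PCA, component screening, BH-FDR, and weight-based selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fcselect import (
    ClinicalSimConfig,
    associate,
    bh_fdr,
    choose_diagnosis_pc,
    fit_pca,
    gen_clinical_dataset,
    label_direction,
    patient_indicator,
    pca_pipeline,
    project_scores,
    select_features,
)
from fcselect.fc_core import InputError
from fcselect.pca_select import PCModel, SelectionResult


class TestFitPCA:
    def test_rank_one_data(self, rng, make_fc_dataset):
        latent = rng.standard_normal(30)
        loading = rng.standard_normal(20)
        data = make_fc_dataset(np.outer(latent, loading))
        pc = fit_pca(data)
        assert pc.explained_variance_fraction[0] > 1 - 1e-9

    def test_component_count_is_n_minus_one(self, rng, make_fc_dataset):
        pc = fit_pca(make_fc_dataset(rng.standard_normal((50, 200))))
        assert pc.n_components == 49
        assert np.all(np.diff(pc.explained_variance_fraction) <= 1e-12)

    def test_orthonormal_weights_and_score_relation(self, rng, make_fc_dataset):
        data = make_fc_dataset(rng.standard_normal((25, 40)))
        pc = fit_pca(data)
        gram = pc.weights @ pc.weights.T
        np.testing.assert_allclose(gram, np.eye(pc.n_components), atol=1e-8)
        centered = data.values - pc.feature_means
        np.testing.assert_allclose(pc.scores, centered @ pc.weights.T,
                                   atol=1e-8)
        # full reconstruction of the centred data
        np.testing.assert_allclose(pc.scores @ pc.weights, centered,
                                   atol=1e-6)

    def test_matches_covariance_eigendecomposition(self, rng, make_fc_dataset):
        # independent oracle on a 20 x 30 instance
        data = make_fc_dataset(rng.standard_normal((20, 30)))
        pc = fit_pca(data)
        centered = data.values - data.values.mean(axis=0)
        cov = centered.T @ centered / 1.0
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: pc.n_components]
        for k in range(pc.n_components):
            v = evecs[:, order[k]]
            dot = abs(v @ pc.weights[k])
            assert dot > 1 - 1e-8
        np.testing.assert_allclose(
            pc.explained_variance_fraction,
            evals[order] / evals.sum(), atol=1e-8,
        )

    def test_deterministic_sign_convention(self, rng, make_fc_dataset):
        data = make_fc_dataset(rng.standard_normal((15, 25)))
        pc = fit_pca(data)
        peaks = pc.weights[np.arange(pc.n_components),
                           np.argmax(np.abs(pc.weights), axis=1)]
        assert (peaks > 0).all()

    def test_too_few_subjects_rejected(self, make_fc_dataset):
        with pytest.raises(InputError):
            fit_pca(make_fc_dataset(np.zeros((2, 5))))


class TestProjectScores:
    def test_training_projection_reproduces_scores(self, rng, make_fc_dataset):
        data = make_fc_dataset(rng.standard_normal((20, 30)))
        pc = fit_pca(data)
        np.testing.assert_allclose(project_scores(pc, 0, data),
                                   pc.scores[:, 0], atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng, make_fc_dataset):
        pc = fit_pca(make_fc_dataset(rng.standard_normal((10, 12))))
        with pytest.raises(InputError):
            project_scores(pc, 0, make_fc_dataset(rng.standard_normal((4, 9))))


class TestBHFDR:
    def test_handbook_examples(self):
        rej, _ = bh_fdr([0.2, 0.9])
        assert not rej.any()
        rej, _ = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_array_equal(rej, [True, True, True, False])
        rej, _ = bh_fdr([0.04])
        assert rej.all()

    def test_empty_input(self):
        rej, adj = bh_fdr([])
        assert rej.size == 0 and adj.size == 0

    @staticmethod
    def _brute_force_step_up(p, q):
        p = np.asarray(p)
        order = np.argsort(p)
        m = p.size
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_max = k
        rejected = np.zeros(m, dtype=bool)
        if k_max:
            rejected[order[:k_max]] = True
        return rejected

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_brute_force_enumeration(self, p, q):
        rej, adj = bh_fdr(p, q=q)
        np.testing.assert_array_equal(rej, self._brute_force_step_up(p, q))
        assert ((adj >= 0) & (adj <= 1)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.2])


class TestAssociate:
    @staticmethod
    def _planted(seed, effect=1.0):
        cfg = ClinicalSimConfig(
            n_control=200, n_patient=200, n_features=600,
            disorder_effect=effect, n_disorder_fcs=30, site_bias_sd=0.0,
            site_scale_sd=0.0, age_effect=0.0, sex_effect=0.0, seed=seed,
        )
        return gen_clinical_dataset(cfg)

    def test_planted_component_is_flagged(self):
        hits = 0
        for seed in range(10):
            data, pheno, _ = self._planted(seed)
            pc = fit_pca(data)
            assoc = associate(pc, pheno, ["diagnosis"])
            comp = choose_diagnosis_pc(assoc, pc)
            hits += comp == 0
        assert hits >= 9

    def test_null_family_control_is_nominal(self):
        # shuffled labels: the fraction of runs flagging any component
        # stays near the BH family level
        data, pheno, _ = self._planted(0, effect=0.0)
        pc = fit_pca(data)
        rng = np.random.default_rng(7)
        flags = 0
        reps = 60
        for _ in range(reps):
            shuffled = pheno.copy()
            shuffled["diagnosis"] = rng.permutation(
                pheno["diagnosis"].to_numpy()
            )
            assoc = associate(pc, shuffled, ["diagnosis"])
            flags += assoc["significant"].any()
        assert flags / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_factor_equal_to_scores_is_perfectly_correlated(self, rng,
                                                            make_fc_dataset):
        data = make_fc_dataset(rng.standard_normal((30, 20)))
        pc = fit_pca(data)
        pheno = pd.DataFrame({"probe": pc.scores[:, 0]})
        assoc = associate(pc, pheno, ["probe"])
        row = assoc[(assoc["component"] == 0)].iloc[0]
        assert row["test"] == "pearson_r"
        assert abs(row["statistic"] - 1.0) < 1e-9
        assert row["p"] < 1e-12

    def test_factor_test_types(self, small_clinical):
        data, pheno, _ = small_clinical
        pc = fit_pca(data)
        assoc = associate(
            pc, pheno,
            ["diagnosis", "sex", "site", "age", "symptom_score", "mean_fd"],
        )
        kinds = assoc.groupby("factor")["test"].first()
        assert kinds["diagnosis"] == "t" and kinds["sex"] == "t"
        assert kinds["site"] == "anova_F"
        assert {kinds["age"], kinds["symptom_score"], kinds["mean_fd"]} == {
            "pearson_r"
        }

    def test_small_site_under_anova_rejected(self, small_clinical):
        data, pheno, _ = small_clinical
        pc = fit_pca(data)
        broken = pheno.copy()
        broken.loc[broken.index[:1], "site"] = "lonely"
        with pytest.raises(InputError, match="lonely"):
            associate(pc, broken, ["site"])


class TestChooseDiagnosisPC:
    @staticmethod
    def _assoc(rows):
        return pd.DataFrame(rows)

    @staticmethod
    def _model(fracs):
        k = len(fracs)
        return PCModel(
            weights=np.eye(k), scores=np.zeros((3, k)),
            explained_variance_fraction=np.asarray(fracs),
            feature_means=np.zeros(k),
        )

    def test_null_when_nothing_significant(self):
        assoc = self._assoc([
            {"factor": "diagnosis", "component": 0, "significant": False},
        ])
        assert choose_diagnosis_pc(assoc, self._model([0.5])) is None

    def test_single_significant_component(self):
        assoc = self._assoc([
            {"factor": "diagnosis", "component": 1, "significant": True},
            {"factor": "diagnosis", "component": 0, "significant": False},
        ])
        assert choose_diagnosis_pc(assoc, self._model([0.5, 0.2])) == 1

    def test_highest_explained_variance_wins(self):
        assoc = self._assoc([
            {"factor": "diagnosis", "component": 1, "significant": True},
            {"factor": "diagnosis", "component": 3, "significant": True},
        ])
        model = self._model([0.5, 0.03, 0.1, 0.08])
        assert choose_diagnosis_pc(assoc, model) == 3


class TestSelectFeatures:
    def test_single_outlier_weight_selected(self, rng):
        w = rng.standard_normal(1000)
        w /= np.linalg.norm(w)
        z_scale = w.std()
        w[137] = 8 * z_scale
        pc = PCModel(
            weights=w[None, :], scores=np.zeros((5, 1)),
            explained_variance_fraction=np.array([1.0]),
            feature_means=np.zeros(1000),
        )
        sel = select_features(pc, 0)
        assert 137 in sel.positions
        assert sel.n_selected <= 3  # BH keeps the null tail out

    def test_degenerate_component_rejected(self):
        pc = PCModel(
            weights=np.full((1, 10), 0.3), scores=np.zeros((5, 1)),
            explained_variance_fraction=np.array([1.0]),
            feature_means=np.zeros(10),
        )
        with pytest.raises(InputError, match="degenerate"):
            select_features(pc, 0)

    def test_aggressive_percentile_variant(self, rng):
        w = rng.standard_normal(500)
        pc = PCModel(
            weights=w[None, :], scores=np.zeros((5, 1)),
            explained_variance_fraction=np.array([1.0]),
            feature_means=np.zeros(500),
        )
        sel = select_features(pc, 0, top_percentile=98.0)
        assert sel.method == "pca_aggressive"
        assert 8 <= sel.n_selected <= 12

    def test_planted_recovery_sensitivity_precision(self):
        cfg = ClinicalSimConfig(
            n_control=200, n_patient=200, n_features=1000,
            disorder_effect=0.8, n_disorder_fcs=50, site_bias_sd=0.0,
            site_scale_sd=0.0, age_effect=0.0, sex_effect=0.0, seed=2,
        )
        data, pheno, truth = gen_clinical_dataset(cfg)
        sel, pc, _ = pca_pipeline(data, pheno)
        tp = np.intersect1d(sel.positions, truth["disorder_idx"]).size
        assert tp / truth["disorder_idx"].size >= 0.9
        assert tp / sel.n_selected >= 0.9


class TestLabelDirection:
    def test_over_and_under(self, make_fc_dataset):
        values = np.array([[0.1, 0.5], [0.1, 0.5], [0.2, 0.3], [0.2, 0.3]])
        data = make_fc_dataset(values)
        pheno = pd.DataFrame({
            "diagnosis": ["HC", "HC", "MDD", "MDD"],
        })
        sel = SelectionResult("pca", np.array([0, 1]), 2)
        sel = label_direction(data, pheno, sel)
        np.testing.assert_array_equal(sel.direction, ["over", "under"])

    def test_swapping_groups_flips_directions(self, rng, make_fc_dataset):
        data = make_fc_dataset(rng.standard_normal((20, 6)))
        pheno = pd.DataFrame({"diagnosis": ["HC"] * 10 + ["MDD"] * 10})
        flipped = pd.DataFrame({"diagnosis": ["MDD"] * 10 + ["HC"] * 10})
        sel_a = label_direction(
            data, pheno, SelectionResult("pca", np.arange(6), 6)
        )
        sel_b = label_direction(
            data, flipped, SelectionResult("pca", np.arange(6), 6)
        )
        assert all(a != b for a, b in zip(sel_a.direction, sel_b.direction))

    def test_planted_positive_loadings_labelled_over(self, small_clinical):
        data, pheno, truth = small_clinical
        sel = SelectionResult("pca", truth["disorder_idx"], data.n_features)
        sel = label_direction(data, pheno, sel)
        assert (sel.direction == "over").mean() > 0.95


class TestEndToEndNullControl:
    def test_pure_noise_yields_null_mostly(self):
        # family-level BH control across components (light version; the
        # full 200-replicate check lives in the acceptance suite)
        nulls = 0
        reps = 40
        for seed in range(reps):
            cfg = ClinicalSimConfig(
                n_control=60, n_patient=60, n_features=300,
                disorder_effect=0.0, site_bias_sd=0.0, site_scale_sd=0.0,
                age_effect=0.0, sex_effect=0.0, seed=3000 + seed,
            )
            data, pheno, _ = gen_clinical_dataset(cfg)
            sel, _, _ = pca_pipeline(data, pheno)
            nulls += sel is None
        assert nulls / reps >= 0.9
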