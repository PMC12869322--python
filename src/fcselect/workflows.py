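"""Desk-scale reference workflows tying the pipeline stages together.

Each function runs one of the package's headline analyses end to end on
synthetic data with known ground truth and returns the measured
quantities: family-level null control of the component screen, planted-
component recovery and cross-cohort projection, the selector robustness
comparison on the confounded benchmark, harmonization quality, and
traveling-subject variance-component recovery.  The same entry points
back the acceptance checks and the reproduction script, so every reported
number is recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .baselines import (
    ensemble_fit,
    evaluate_classifier,
    lasso_select,
    pca_inner_selector,
    ttest_select,
)
from .evaluate import effect_summary, hedges_g, selection_overlap
from .fc_core import FCDataset, patient_indicator
from .harmonize import combat, covariate_design, traveling_bias_estimate
from .pca_select import pca_pipeline, project_scores
from .synthgen import (
    BENCHMARK_LASSO_PARAMS,
    ClinicalSimConfig,
    TravelingSimConfig,
    benchmark_validation_overrides,
    gen_clinical_dataset,
    gen_discovery_validation_pair,
    gen_traveling_subject,
)


def null_control_rate(n_repeats: int = 200, n_per_group: int = 100,
                      n_features: int = 1000, seed: int = 0) -> float:
    """Fraction of pure-noise cohorts in which no diagnosis component is found.

    Draws ``n_repeats`` independent cohorts with no planted effect, runs
    the full PCA + screening pipeline, and counts null outcomes.  With
    BH control across components the null rate should stay near or above
    ``1 - q``.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, n_repeats)
    nulls = 0
    for s in sub_seeds:
        cfg = ClinicalSimConfig(
            n_control=n_per_group, n_patient=n_per_group,
            n_features=n_features, disorder_effect=0.0, site_bias_sd=0.0,
            site_scale_sd=0.0, age_effect=0.0, sex_effect=0.0, seed=int(s),
        )
        data, pheno, _ = gen_clinical_dataset(cfg)
        selection, _, _ = pca_pipeline(data, pheno)
        nulls += selection is None
    return nulls / n_repeats


def recovery_study(seeds=(0, 1, 2, 3, 4), disorder_effect: float = 0.8,
                   validation_effect: float = 0.5) -> dict:
    """Planted-component recovery and cross-cohort score projection.

    For each replicate pair (50 planted FCs of 1,000, 400 subjects):
    select features on the discovery cohort and score sensitivity /
    precision against the planted set, then project the discovery
    component's weights onto the validation cohort and t-test the
    projected scores between groups.  Returns means over replicates.
    """
    sens, prec, proj_p, jaccard = [], [], [], []
    for seed in seeds:
        cfg = ClinicalSimConfig(
            n_control=200, n_patient=200, n_features=1000,
            disorder_effect=disorder_effect, n_disorder_fcs=50,
            site_bias_sd=0.0, site_scale_sd=0.0, age_effect=0.0,
            sex_effect=0.0, seed=seed,
        )
        (disc, disc_ph), (val, val_ph), truth = gen_discovery_validation_pair(
            cfg, {"disorder_effect": validation_effect}
        )
        selection, pc, _ = pca_pipeline(disc, disc_ph)
        if selection is None:
            sens.append(0.0)
            prec.append(0.0)
            proj_p.append(1.0)
            jaccard.append(0.0)
            continue
        planted = truth["disorder_idx"]
        tp = np.intersect1d(selection.positions, planted).size
        sens.append(tp / planted.size)
        prec.append(tp / selection.n_selected)
        jaccard.append(tp / (planted.size + selection.n_selected - tp))
        scores = project_scores(pc, selection.component, val)
        y = patient_indicator(val_ph)
        proj_p.append(
            float(stats.ttest_ind(scores[y == 1], scores[y == 0])[1])
        )
    return {
        "sensitivity": float(np.mean(sens)),
        "precision": float(np.mean(prec)),
        "jaccard": float(np.mean(jaccard)),
        "max_projection_p": float(np.max(proj_p)),
        "n_replicates": len(list(seeds)),
    }


def robustness_comparison(seeds=(0, 1, 2, 3, 4), lasso_params=None) -> dict:
    """Selector comparison on the shipped confounded benchmark.

    Generates replicate discovery/validation pairs from
    :meth:`ClinicalSimConfig.confounded_benchmark`, runs all four
    selectors on each discovery cohort (plus PCA and LASSO on the
    validation cohort for stability), and returns the mean |g| per
    method and dataset together with mean selection overlaps across the
    pair.  Orderings are reported on replicate means because single-pair
    orderings fluctuate.
    """
    lasso_params = dict(BENCHMARK_LASSO_PARAMS if lasso_params is None
                        else lasso_params)
    disc_means: dict[str, list] = {}
    val_means: dict[str, list] = {}
    ov_pca, ov_lasso = [], []
    for seed in seeds:
        cfg = ClinicalSimConfig.confounded_benchmark(seed=seed)
        (disc, disc_ph), (val, val_ph), _ = gen_discovery_validation_pair(
            cfg, benchmark_validation_overrides()
        )
        y_d = patient_indicator(disc_ph)
        y_v = patient_indicator(val_ph)
        g_d = hedges_g(disc, y_d)
        g_v = hedges_g(val, y_v)

        sel_pca, _, _ = pca_pipeline(disc, disc_ph)
        sel_pca_v, _, _ = pca_pipeline(val, val_ph)
        selections = [
            sel_pca,
            lasso_select(disc, y_d, random_state=seed, **lasso_params),
            ttest_select(disc, y_d, "fdr_bh"),
            ttest_select(disc, y_d, "bonferroni"),
        ]
        sel_lasso_v = lasso_select(val, y_v, random_state=seed + 100,
                                   **lasso_params)
        table = effect_summary(
            {"discovery": g_d, "validation": g_v}, selections
        )
        for _, row in table.iterrows():
            target = disc_means if row["dataset"] == "discovery" else val_means
            target.setdefault(row["method"], []).append(row["mean"])
        ov_pca.append(selection_overlap(sel_pca, sel_pca_v)[0])
        ov_lasso.append(selection_overlap(selections[1], sel_lasso_v)[0])
    return {
        "discovery_mean_g": {k: float(np.mean(v)) for k, v in disc_means.items()},
        "validation_mean_g": {k: float(np.mean(v)) for k, v in val_means.items()},
        "overlap_pca": float(np.mean(ov_pca)),
        "overlap_lasso": float(np.mean(ov_lasso)),
        "n_replicates": len(list(seeds)),
    }


def harmonization_study(seed: int = 11) -> dict:
    """ComBat equalization/preservation and traveling-bias recovery.

    Returns the maximum post-harmonization between-site mean gap
    (shrinkage-free run), the shift in the planted diagnosis effect's
    mean Hedge's g under the covariate-preserving EB run, and the
    maximum error of traveling-subject site-bias recovery on a fully
    crossed 9 x 12 x 2 design with planted offsets.
    """
    cfg = ClinicalSimConfig(
        n_control=150, n_patient=150, n_features=300, disorder_effect=0.5,
        n_disorder_fcs=30, n_sites=2, site_bias_sd=0.3, site_scale_sd=0.1,
        age_effect=0.05, sex_effect=0.05, seed=seed,
    )
    data, pheno, truth = gen_clinical_dataset(cfg)
    site = pheno["site"].to_numpy()
    y = patient_indicator(pheno)

    plain, _ = combat(data, site, eb=False)
    means = [plain.values[site == s].mean(axis=0) for s in np.unique(site)]
    site_mean_gap = float(np.abs(means[0] - means[1]).max())

    design, names = covariate_design(pheno, ["diagnosis", "age", "sex"])
    preserved, _ = combat(data, site, design, names, eb=True)
    g_before = hedges_g(data, y)[truth["disorder_idx"]].mean()
    g_after = hedges_g(preserved, y)[truth["disorder_idx"]].mean()

    ts_cfg = TravelingSimConfig(
        n_participants=9, n_sites=12, hub_and_spoke=False, runs_per_visit=2,
        n_features=50, sd_participant=0.15, sd_scanner=0.0, sd_protocol=0.0,
        sd_session=0.01, seed=seed,
    )
    ts, _ = gen_traveling_subject(ts_cfg)
    offsets = np.random.default_rng(seed + 1).normal(0, 0.1, (12, 50))
    offsets -= offsets.mean(axis=0)
    site_idx = ts.labels["site"].str.slice(1).astype(int).to_numpy()
    ts.values = ts.values + offsets[site_idx]
    bias = traveling_bias_estimate(ts)
    order = np.argsort(bias.sites)
    bias_err = float(np.abs(bias.bias[order] - offsets).max())

    return {
        "site_mean_gap": site_mean_gap,
        "g_shift": float(abs(g_after - g_before)),
        "g_planted_before": float(g_before),
        "g_planted_after": float(g_after),
        "ts_bias_max_error": bias_err,
    }


def variance_decomposition_study(seed: int = 0) -> dict:
    """Factor-SD recovery at the reference traveling-subject design size.

    75 participants x 3 sites x 2 runs with generator SDs
    0.17 / 0.06 / 0.19 / 0.05 (participant / scanner / session /
    protocol); reports the per-factor mean estimates over FC features.
    """
    from .evaluate import factor_variability

    ts, _ = gen_traveling_subject(TravelingSimConfig(seed=seed))
    summary = factor_variability(ts).table.mean()
    return {
        "participant_sd": float(summary["participant"]),
        "scanner_sd": float(summary["scanner"]),
        "session_sd": float(summary["session"]),
        "protocol_sd": float(summary["protocol"]),
        "true_sds": {"participant": 0.17, "scanner": 0.06,
                     "session": 0.19, "protocol": 0.05},
    }


def leakage_probe(seed: int = 21) -> dict:
    """Ensemble no-leakage sentinel.

    Fits the ensemble (PCA selection inside each training subsample) on a
    discovery cohort, then evaluates it on a validation cohort twice:
    clean, and with one feature overwritten by the test labels.  Without
    leakage the sentinel cannot raise the AUC beyond noise.
    """
    cfg = ClinicalSimConfig(
        n_control=120, n_patient=120, n_features=500, disorder_effect=0.8,
        latent_sd=1.0, n_disorder_fcs=15, site_bias_sd=0.05,
        site_scale_sd=0.0, age_effect=0.0, sex_effect=0.0, seed=seed,
    )
    (disc, disc_ph), (val, val_ph), _ = gen_discovery_validation_pair(cfg)
    y_d = patient_indicator(disc_ph)
    y_v = patient_indicator(val_ph)
    model = ensemble_fit(disc, y_d, n_subsamples=6, cv=4,
                         inner_selector=pca_inner_selector(),
                         random_state=seed)
    clean = evaluate_classifier(model, val, y_v)
    spiked = val.values.copy()
    spiked[:, 7] = y_v.astype(float)
    sentinel = evaluate_classifier(
        model, FCDataset(spiked, val.feature_index, val.subject_ids), y_v
    )
    return {
        "clean_auc": float(clean.auc),
        "sentinel_auc": float(sentinel.auc),
        "auc_inflation": float(sentinel.auc - clean.auc),
        "mean_selected": model.mean_selected,
    }
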