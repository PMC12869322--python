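"""Synthetic clinical FC datasets and traveling-subject designs.

The clinical generator emulates a multi-site case-control resting-state
connectivity study directly on the Fisher-z scale: a sparse latent disorder
component shifts patients' means on a known set of FC features, imaging
sites add feature-wise offsets and multiplicative scales (the same
location/scale form the ComBat harmonization model assumes), age and sex
load on dense covariate directions, and the rest is i.i.d. Gaussian noise.
Every planted quantity is returned as ground truth so downstream selection,
harmonization, and effect-size code can be audited against it.

The traveling-subject generator emulates a hub-and-spoke repeat-measurement
design in which each participant is scanned at several sites, producing an
additive decomposition per run::

    value = grand mean + participant + scanner + protocol + session + noise

with independently configurable SDs per factor, the design used for
variance-component estimation.

Two optional confound mechanisms exist for robustness experiments
(``confounded_distractor``): a small block of high-amplitude FC features
whose site offsets correlate with diagnosis through biased site assignment,
and a broader block of weak effects carried by a protocol-like binary
covariate that is likewise diagnosis-confounded.  Both produce apparent
case-control differences that do not generalize to a cohort with unbiased
assignment, mimicking site-driven overfitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc_core import (
    FCDataset,
    ROIRun,
    TravelingSubjectSet,
    all_pairs,
    n_pairs,
    synthetic_pairs,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ClinicalSimConfig:
    """Conditions of a simulated case-control FC study.

    Parameters
    ----------
    n_control, n_patient:
        Group sizes.
    n_features:
        FC dimensionality.  ``n_rois`` may be given instead, implying
        ``n_rois * (n_rois - 1) / 2`` features.
    disorder_effect:
        Standardized mean shift of patients on the latent disorder factor
        (per unit loading; loadings are 1, so with unit noise and
        ``latent_sd=0`` this is the population Hedge's g of each planted
        feature).
    n_disorder_fcs:
        Number of FC features carrying the disorder component.
    latent_sd:
        Within-subject SD of the latent disorder factor.  With 0 (the
        default) the factor is the pure group indicator and per-feature
        effect sizes equal ``disorder_effect``; positive values add shared
        individual variability on the factor, which bounds how separable
        the groups can be no matter how many planted features a classifier
        combines (the realistic regime for robustness comparisons).
    site_labels:
        Assignment scheme, ``"balanced"`` (round-robin within group) or
        ``"confounded"`` (patients preferentially assigned to site 1).
    site_bias_sd, site_scale_sd:
        SDs of per-(site, feature) additive offsets and log multiplicative
        scales.
    age_effect, sex_effect:
        Loading magnitudes of the dense age / sex covariate directions.
    noise_sd:
        Residual SD on the Fisher-z scale.
    confounded_distractor:
        Plant the two confound blocks described in the module docstring.
    """

    n_control: int = 200
    n_patient: int = 200
    n_features: int = 1000
    n_rois: int | None = None
    disorder_effect: float = 0.5
    n_disorder_fcs: int = 50
    latent_sd: float = 0.0
    loading_sd: float = 0.0
    n_sites: int = 2
    site_labels: str = "balanced"
    site_bias_sd: float = 0.1
    site_scale_sd: float = 0.05
    age_effect: float = 0.1
    sex_effect: float = 0.1
    noise_sd: float = 1.0
    confounded_distractor: bool = False
    n_distractor_fcs: int = 8
    distractor_magnitude: float = 1.2
    distractor_noise_sd: float = 1.0
    n_weak_fcs: int = 400
    weak_magnitude: float = 0.19
    weak_noise_sd: float = 0.5
    confound_strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_rois is not None:
            self.n_features = n_pairs(self.n_rois)
        for name in ("n_control", "n_patient", "n_features", "n_disorder_fcs",
                     "n_sites"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_control + self.n_patient < 4:
            raise ConfigError("need at least 4 subjects in total")
        for name in ("site_bias_sd", "site_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_disorder_fcs > self.n_features:
            raise ConfigError("n_disorder_fcs cannot exceed n_features")
        if self.site_labels not in ("balanced", "confounded"):
            raise ConfigError(f"unknown site_labels scheme {self.site_labels!r}")
        if not 0.0 <= self.confound_strength < 1.0:
            raise ConfigError("confound_strength must be in [0, 1)")

    @classmethod
    def confounded_benchmark(cls, seed: int = 0) -> "ClinicalSimConfig":
        """The shipped discovery-cohort conditions for robustness comparisons.

        A sparse disorder component carried by a *noisy* latent factor
        (``latent_sd=1``, so the planted per-feature Hedge's g is about
        0.5 and joint discriminability is bounded), plus both confound
        blocks: a few site-correlated distractors whose apparent discovery
        SNR exceeds the true features', and many weak covariate-carried
        effects on low-variance features.  Pair it with
        ``benchmark_validation_overrides()`` to obtain a validation cohort
        in which only the true component generalizes.
        """
        return cls(
            n_control=200,
            n_patient=200,
            n_features=1000,
            disorder_effect=0.7,
            latent_sd=1.0,
            loading_sd=0.5,
            n_disorder_fcs=50,
            n_sites=2,
            site_labels="confounded",
            site_bias_sd=0.05,
            site_scale_sd=0.0,
            age_effect=0.0,
            sex_effect=0.0,
            noise_sd=1.0,
            confounded_distractor=True,
            seed=seed,
        )


def benchmark_validation_overrides() -> dict:
    """Overrides turning the benchmark discovery config into its validation twin."""
    return {"confounded_distractor": False, "site_labels": "balanced"}


#: Subsampled-LASSO settings used alongside the confounded benchmark for
#: desk-scale method comparisons: few subsamples with high member diversity
#: (fraction 0.6) and a 7-of-10 stability threshold.
BENCHMARK_LASSO_PARAMS = {
    "n_subsamples": 10,
    "cv": 4,
    "subsample_fraction": 0.6,
    "selection_count_threshold": 7,
}


@dataclass
class TravelingSimConfig:
    """Conditions of a simulated traveling-subject dataset.

    Per-factor SDs default to the magnitudes observed for participant,
    scanner, session, and protocol variability in multi-site repeat
    measurements of selected FCs (0.17 / 0.06 / 0.19 / 0.05 on the
    Fisher-z scale).  ``sd_noise`` is extra i.i.d. measurement noise on
    top of the run-level session term and defaults to 0 because the
    session term already is the run-level residual.
    """

    n_participants: int = 75
    n_sites: int = 17
    n_hubs: int = 3
    n_scanners: int = 6
    n_protocols: int = 3
    sites_per_participant: int = 3
    runs_per_visit: int = 2
    n_features: int = 100
    sd_participant: float = 0.17
    sd_scanner: float = 0.06
    sd_session: float = 0.19
    sd_protocol: float = 0.05
    sd_noise: float = 0.0
    hub_and_spoke: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_sites", "n_scanners", "n_protocols",
                     "sites_per_participant", "runs_per_visit", "n_features"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("sd_participant", "sd_scanner", "sd_session",
                     "sd_protocol", "sd_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.hub_and_spoke:
            if self.n_sites < 2:
                raise ConfigError("hub_and_spoke needs at least 2 sites")
            if self.sites_per_participant < 2:
                raise ConfigError(
                    "hub_and_spoke requires each participant to visit >= 2 sites"
                )
            if self.n_hubs < 1 or self.n_hubs >= self.n_sites:
                raise ConfigError("n_hubs must be in [1, n_sites)")
            if self.sites_per_participant > self.n_sites:
                raise ConfigError("sites_per_participant cannot exceed n_sites")


# ---------------------------------------------------------------------------
# clinical generator
# ---------------------------------------------------------------------------

def _plant_structure(cfg: ClinicalSimConfig, rng: np.random.Generator) -> dict:
    """Draw everything shared between paired cohorts: planted indices and loadings."""
    perm = rng.permutation(cfg.n_features)
    k = cfg.n_disorder_fcs
    # lognormal loading magnitudes (all 1 when loading_sd = 0): a handful
    # of FCs express the latent factor more strongly than the rest
    loading = (
        np.exp(rng.normal(0.0, cfg.loading_sd, k))
        if cfg.loading_sd > 0 else np.ones(k)
    )
    structure = {
        "disorder_idx": np.sort(perm[:k]),
        "loading": loading,
        "distractor_idx": np.sort(perm[k:k + cfg.n_distractor_fcs]),
        "weak_idx": np.sort(
            perm[k + cfg.n_distractor_fcs:
                 k + cfg.n_distractor_fcs + cfg.n_weak_fcs]
        ),
        "age_loading": rng.standard_normal(cfg.n_features),
        "sex_loading": rng.standard_normal(cfg.n_features),
    }
    return structure


def _assign_sites(cfg: ClinicalSimConfig, patient: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    n = patient.size
    if cfg.site_labels == "balanced" or cfg.n_sites == 1:
        site = np.empty(n, dtype=int)
        for g in (0, 1):
            idx = np.flatnonzero(patient == g)
            site[idx] = np.arange(idx.size) % cfg.n_sites
        return site
    # confounded: patients land at site 0 with elevated probability
    p_pat = 0.5 + cfg.confound_strength / 2.0
    p_con = 0.5 - cfg.confound_strength / 2.0
    at_zero = rng.random(n) < np.where(patient == 1, p_pat, p_con)
    site = np.where(
        at_zero, 0, 1 + rng.integers(0, max(cfg.n_sites - 1, 1), size=n)
    )
    return site


def _generate_clinical(cfg: ClinicalSimConfig, structure: dict,
                       rng: np.random.Generator,
                       id_prefix: str) -> tuple[FCDataset, pd.DataFrame]:
    n = cfg.n_control + cfg.n_patient
    m = cfg.n_features
    patient = np.concatenate(
        [np.zeros(cfg.n_control, dtype=int), np.ones(cfg.n_patient, dtype=int)]
    )
    site = _assign_sites(cfg, patient, rng)

    age = np.clip(rng.normal(40.0, 12.0, n), 18, 80)
    male = rng.integers(0, 2, n)
    mean_fd = np.clip(rng.normal(0.12, 0.04, n), 0.02, None)

    gamma = rng.normal(0.0, cfg.site_bias_sd, (cfg.n_sites, m))
    scale = np.exp(rng.normal(0.0, cfg.site_scale_sd, (cfg.n_sites, m)))
    eps = rng.normal(0.0, cfg.noise_sd, (n, m))
    if cfg.confounded_distractor:
        # distractor block: a site-0 offset which, through diagnosis-biased
        # site assignment, produces a high-SNR apparent group difference
        # with no biological counterpart; weak block: many small effects
        # carried by a second confounded covariate, on low-variance features
        gamma[0, structure["distractor_idx"]] += cfg.distractor_magnitude
        if cfg.noise_sd > 0:
            eps[:, structure["distractor_idx"]] *= (
                cfg.distractor_noise_sd / cfg.noise_sd
            )
            eps[:, structure["weak_idx"]] *= cfg.weak_noise_sd / cfg.noise_sd
    values = gamma[site] + scale[site] * eps

    d_idx = structure["disorder_idx"]
    factor = cfg.disorder_effect * patient.astype(float)
    if cfg.latent_sd > 0:
        factor = factor + rng.normal(0.0, cfg.latent_sd, n)
    values[:, d_idx] += factor[:, None] * structure["loading"][None, :]
    age_z = (age - age.mean()) / age.std()
    values += cfg.age_effect * age_z[:, None] * structure["age_loading"][None, :]
    values += (
        cfg.sex_effect * (male - 0.5)[:, None] * structure["sex_loading"][None, :]
    )

    if cfg.confounded_distractor:
        p_pat = 0.5 + cfg.confound_strength / 2.0
        p_con = 0.5 - cfg.confound_strength / 2.0
        covariate = (
            rng.random(n) < np.where(patient == 1, p_pat, p_con)
        ).astype(float)
        values[:, structure["weak_idx"]] += cfg.weak_magnitude * covariate[:, None]

    # symptom score tracks the disorder factor plus measurement noise;
    # a small fraction is missing, as in real questionnaires
    symptom = np.where(
        patient == 1,
        rng.normal(25.0, 8.0, n),
        rng.normal(6.0, 4.0, n),
    )
    symptom = np.clip(symptom, 0.0, 63.0)
    symptom[rng.random(n) < 0.05] = np.nan

    subject_ids = np.array([f"{id_prefix}{k:04d}" for k in range(n)])
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "diagnosis": np.where(patient == 1, "MDD", "HC"),
            "site": np.array([f"site{int(s):02d}" for s in site]),
            "age": np.round(age, 1),
            "sex": np.where(male == 1, "M", "F"),
            "symptom_score": np.round(symptom, 1),
            "mean_fd": np.round(mean_fd, 4),
        }
    )
    pairs = all_pairs(cfg.n_rois) if cfg.n_rois is not None else synthetic_pairs(m)
    return FCDataset(values, pairs, subject_ids), pheno


def gen_clinical_dataset(
    cfg: ClinicalSimConfig,
) -> tuple[FCDataset, pd.DataFrame, dict]:
    """Generate one clinical cohort with known planted structure.

    Returns ``(dataset, phenotype, ground_truth)`` where the ground truth
    carries the planted feature indices, loadings, and (when the confound
    flag is on) the distractor and weak block indices.
    """
    ss = np.random.SeedSequence(cfg.seed)
    structure_rng, sample_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    structure = _plant_structure(cfg, structure_rng)
    data, pheno = _generate_clinical(cfg, structure, sample_rng, "sub")
    truth = dict(structure)
    if not cfg.confounded_distractor:
        truth["distractor_idx"] = None
        truth["weak_idx"] = None
    return data, pheno, truth


def gen_discovery_validation_pair(
    cfg: ClinicalSimConfig, validation_overrides: dict | None = None,
):
    """Generate paired discovery / validation cohorts sharing planted loadings.

    The pair shares the disorder component (indices and loadings) but has
    independent subjects, independent site-bias realizations, and an
    independently configurable validation design via
    ``validation_overrides`` (e.g. ``{"confounded_distractor": False}``).

    Returns ``((fc_d, pheno_d), (fc_v, pheno_v), ground_truth)``.
    """
    overrides = dict(validation_overrides or {})
    val_cfg = dataclasses.replace(cfg, **overrides)
    if val_cfg.n_features != cfg.n_features:
        raise ConfigError(
            "discovery and validation cohorts must share n_features "
            f"({cfg.n_features} vs {val_cfg.n_features})"
        )
    ss = np.random.SeedSequence(cfg.seed)
    structure_rng, disc_rng, val_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    structure = _plant_structure(cfg, structure_rng)
    disc = _generate_clinical(cfg, structure, disc_rng, "dsc")
    val = _generate_clinical(val_cfg, structure, val_rng, "val")
    truth = dict(structure)
    if not cfg.confounded_distractor:
        truth["distractor_idx"] = None
        truth["weak_idx"] = None
    return disc, val, truth


# ---------------------------------------------------------------------------
# traveling-subject generator
# ---------------------------------------------------------------------------

def gen_traveling_subject(cfg: TravelingSimConfig) -> tuple[TravelingSubjectSet, dict]:
    """Generate a traveling-subject dataset with known per-factor SDs.

    Under the hub-and-spoke design each participant visits one hub site and
    ``sites_per_participant - 1`` random spoke sites; without it every
    participant visits every site (full crossing).  Each visit contributes
    ``runs_per_visit`` runs.  Scanner and protocol are properties of the
    site.  Returns the dataset and the ground-truth factor effects.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss)
    m = cfg.n_features

    # map sites to scanners/protocols; cover every level, rest at random
    scanner_of_site = np.concatenate([
        np.arange(cfg.n_scanners),
        rng.integers(0, cfg.n_scanners, max(cfg.n_sites - cfg.n_scanners, 0)),
    ])[:cfg.n_sites]
    protocol_of_site = np.concatenate([
        np.arange(cfg.n_protocols),
        rng.integers(0, cfg.n_protocols, max(cfg.n_sites - cfg.n_protocols, 0)),
    ])[:cfg.n_sites]
    rng.shuffle(scanner_of_site)
    rng.shuffle(protocol_of_site)

    part_eff = rng.normal(0.0, cfg.sd_participant, (cfg.n_participants, m))
    scan_eff = rng.normal(0.0, cfg.sd_scanner, (cfg.n_scanners, m))
    prot_eff = rng.normal(0.0, cfg.sd_protocol, (cfg.n_protocols, m))

    rows = []
    values = []
    for p in range(cfg.n_participants):
        if cfg.hub_and_spoke:
            hub = int(rng.integers(0, cfg.n_hubs))
            spokes = rng.choice(
                np.arange(cfg.n_hubs, cfg.n_sites),
                size=cfg.sites_per_participant - 1,
                replace=False,
            )
            visited = np.concatenate([[hub], spokes])
        else:
            visited = np.arange(cfg.n_sites)
        for s in visited:
            sc = int(scanner_of_site[s])
            pr = int(protocol_of_site[s])
            for r in range(cfg.runs_per_visit):
                session = rng.normal(0.0, cfg.sd_session, m)
                noise = rng.normal(0.0, cfg.sd_noise, m) if cfg.sd_noise else 0.0
                values.append(
                    part_eff[p] + scan_eff[sc] + prot_eff[pr] + session + noise
                )
                rows.append(
                    {
                        "run_id": f"p{p:03d}_s{s:02d}_r{r}",
                        "participant": f"p{p:03d}",
                        "site": f"s{s:02d}",
                        "scanner": f"scanner{sc}",
                        "protocol": f"protocol{pr}",
                        "session": f"p{p:03d}_s{s:02d}_r{r}",
                    }
                )
    ts = TravelingSubjectSet(
        np.asarray(values), pd.DataFrame(rows), synthetic_pairs(m)
    )
    truth = {
        "participant_effects": part_eff,
        "scanner_effects": scan_eff,
        "protocol_effects": prot_eff,
        "scanner_of_site": scanner_of_site,
        "protocol_of_site": protocol_of_site,
    }
    return ts, truth


# ---------------------------------------------------------------------------
# small time-series generator (exercises fc_core only)
# ---------------------------------------------------------------------------

def gen_roi_timeseries(n_frames: int = 256, n_rois: int = 10,
                       tr_seconds: float = 2.0, n_latent: int = 3,
                       noise_sd: float = 1.0, fd_scale: float = 0.15,
                       seed: int = 0) -> ROIRun:
    """Generate a correlated multi-region run with a plausible FD series.

    Regions mix ``n_latent`` shared slow sinusoidal sources (within the
    resting-state band for the given TR) with independent noise, so the
    resulting correlation matrix is non-trivial.  FD values are drawn from
    a folded normal with occasional spikes; the first frame's FD is 0.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * tr_seconds
    freqs = rng.uniform(0.02, 0.06, n_latent)
    phases = rng.uniform(0, 2 * np.pi, n_latent)
    sources = np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
    mixing = rng.standard_normal((n_latent, n_rois))
    signal = sources @ mixing + noise_sd * rng.standard_normal((n_frames, n_rois))
    fd = np.abs(rng.normal(0.0, fd_scale, n_frames))
    fd[rng.random(n_frames) < 0.05] += rng.uniform(0.5, 1.5)
    fd[0] = 0.0
    return ROIRun(signal=signal, tr_seconds=tr_seconds, fd=fd)
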