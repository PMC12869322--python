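"""Site-effect harmonization of FC datasets.

Two complementary tools:

* **ComBat** — empirical-Bayes location/scale harmonization (Johnson et al.
  2007, parametric priors).  Per feature, each site is modelled as adding an
  offset and rescaling the residual SD; the per-site parameters are shrunk
  across features toward their site-level prior before the data are
  adjusted.  Biological covariates (diagnosis, age, sex) are estimated
  jointly and left in the data — only the site terms are removed.

* **Traveling-subject measurement bias** — when the same participants were
  scanned at several sites, the pure site difference of each FC is directly
  estimable.  Here it is estimated by least squares under the additive
  two-way model ``value = participant + site + residual`` with a
  run-count-weighted sum-to-zero constraint on the site effects, and
  subtracted from clinical data feature-wise.  This additive decomposition
  is a deliberate simplification of full traveling-subject GLM
  harmonization; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .fc_core import FCDataset, InputError, TravelingSubjectSet


class HarmonizeError(ValueError):
    """Harmonization cannot proceed on this input."""


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

@dataclass
class ComBatModel:
    """Fitted ComBat parameters.

    ``gamma_star`` / ``delta_star`` are the (EB-shrunk) per-(site, feature)
    additive and squared-scale parameters on the standardized scale;
    ``grand_mean`` and ``var_pooled`` define the standardization; ``beta``
    holds the covariate coefficients used to reconstruct the per-subject
    standardization mean.
    """

    sites: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    grand_mean: np.ndarray
    var_pooled: np.ndarray
    beta: np.ndarray | None
    covariate_names: tuple[str, ...]
    eb: bool

    def site_position(self, site_labels) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.sites)}
        unseen = sorted({s for s in site_labels if s not in lookup})
        if unseen:
            raise HarmonizeError(f"site(s) {unseen} were not present at fit time")
        return np.asarray([lookup[s] for s in site_labels])


def covariate_design(pheno: pd.DataFrame, columns) -> tuple[np.ndarray, tuple[str, ...]]:
    """Numeric design columns (no intercept) from phenotype covariates.

    Categorical columns are dummy-encoded dropping the first level;
    numeric columns are passed through.
    """
    blocks, names = [], []
    for col in columns:
        series = pheno[col]
        if series.dtype.kind in "ifu":
            blocks.append(series.to_numpy(float)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True)
            blocks.append(dummies.to_numpy(float))
            names.extend(dummies.columns)
    if not blocks:
        return np.empty((len(pheno), 0)), ()
    return np.hstack(blocks), tuple(names)


def _check_full_rank(design: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy QR-style scan
        bad = []
        kept: list[int] = []
        for k in range(design.shape[1]):
            cand = design[:, kept + [k]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(k)
            else:
                bad.append(names[k])
        raise HarmonizeError(
            f"design is rank deficient; collinear column(s): {bad}"
        )


def combat_fit(data: FCDataset, site, covariates: np.ndarray | None = None,
               covariate_names: tuple[str, ...] = (), eb: bool = True,
               max_iter: int = 500, conv: float = 1e-4) -> ComBatModel:
    """Fit ComBat location/scale site parameters.

    Parameters
    ----------
    data:
        Subjects x features FC table.
    site:
        Per-subject site labels.
    covariates:
        Optional subjects x k numeric design (no intercept) of biological
        covariates to preserve, e.g. from :func:`covariate_design`.
    eb:
        Apply parametric empirical-Bayes shrinkage of the per-site
        parameters across features (the standard ComBat behaviour).
        ``eb=False`` uses the raw per-site estimates, which reduces to
        exact per-site standardization.
    """
    y = data.values
    site = np.asarray(site)
    sites, site_idx = np.unique(site, return_inverse=True)
    n_sites = sites.size
    n, m = y.shape
    if n_sites < 2:
        raise HarmonizeError("ComBat needs at least 2 sites")
    counts = np.bincount(site_idx, minlength=n_sites)
    small = sites[counts < 2]
    if small.size:
        raise HarmonizeError(f"site(s) {list(small)} have fewer than 2 subjects")

    batch = np.zeros((n, n_sites))
    batch[np.arange(n), site_idx] = 1.0
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape[0] != n:
        raise InputError("covariate rows must match subject count")
    design = np.hstack([batch, covariates])
    names = [f"site[{s}]" for s in sites] + list(
        covariate_names or [f"x{k}" for k in range(covariates.shape[1])]
    )
    _check_full_rank(design, names)

    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    gamma_hat_raw = b_hat[:n_sites]
    beta = b_hat[n_sites:] if covariates.shape[1] else None
    grand_mean = (counts / n) @ gamma_hat_raw
    resid = y - design @ b_hat
    var_pooled = (resid ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise HarmonizeError("zero pooled variance feature(s); cannot standardize")

    stand_mean = grand_mean[None, :] + (
        covariates @ beta if beta is not None else 0.0
    )
    z = (y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.vstack([z[site_idx == b].mean(axis=0) for b in range(n_sites)])
    delta_hat = np.vstack(
        [z[site_idx == b].var(axis=0, ddof=1) for b in range(n_sites)]
    )

    if not eb:
        gamma_star, delta_star = gamma_hat, delta_hat
    else:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for b in range(n_sites):
            g_bar = gamma_hat[b].mean()
            t2 = gamma_hat[b].var(ddof=1)
            d_mean = delta_hat[b].mean()
            d_var = delta_hat[b].var(ddof=1)
            # moment-matched inverse-gamma prior for the scale parameters
            a_prior = (2 * d_var + d_mean ** 2) / d_var
            b_prior = (d_mean * d_var + d_mean ** 3) / d_var
            gamma_star[b], delta_star[b] = _eb_iterate(
                z[site_idx == b], gamma_hat[b], delta_hat[b],
                g_bar, t2, a_prior, b_prior, max_iter, conv,
            )

    return ComBatModel(
        sites=sites,
        gamma_star=gamma_star,
        delta_star=delta_star,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        beta=beta,
        covariate_names=tuple(covariate_names),
        eb=eb,
    )


def _eb_iterate(z_site, gamma_hat, delta_hat, g_bar, t2, a_prior, b_prior,
                max_iter, conv):
    """Iterative parametric EB posterior estimates for one site."""
    n_b = z_site.shape[0]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (t2 * n_b * gamma_hat + delta * g_bar) / (t2 * n_b + delta)
        sum2 = ((z_site - gamma_new[None, :]) ** 2).sum(axis=0)
        delta_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs((gamma_new - gamma) / np.where(gamma == 0, 1.0, gamma)).max(),
            np.abs((delta_new - delta) / delta).max(),
        )
        gamma, delta = gamma_new, delta_new
        if change < conv:
            break
    return gamma, delta


def combat_apply(model: ComBatModel, data: FCDataset, site,
                 covariates: np.ndarray | None = None) -> FCDataset:
    """Adjust a dataset with fitted ComBat parameters (site terms removed).

    ``covariates`` must match the design used at fit time (pass the same
    columns for the new subjects); they are used only to reconstruct each
    subject's standardization mean so that biological variance is preserved.
    """
    pos = model.site_position(np.asarray(site))
    y = data.values
    if model.beta is not None:
        if covariates is None:
            raise HarmonizeError(
                "model was fitted with covariates; pass matching covariates"
            )
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape != (y.shape[0], model.beta.shape[0]):
            raise InputError("covariate design shape does not match the model")
        stand_mean = model.grand_mean[None, :] + covariates @ model.beta
    else:
        stand_mean = np.broadcast_to(model.grand_mean[None, :], y.shape)
    scale = np.sqrt(model.var_pooled)[None, :]
    z = (y - stand_mean) / scale
    adjusted = (z - model.gamma_star[pos]) / np.sqrt(model.delta_star[pos])
    out = adjusted * scale + stand_mean
    return FCDataset(out, data.feature_index, data.subject_ids)


def combat(data: FCDataset, site, covariates: np.ndarray | None = None,
           covariate_names: tuple[str, ...] = (),
           eb: bool = True) -> tuple[FCDataset, ComBatModel]:
    """Convenience: fit on a dataset and harmonize it in one step."""
    model = combat_fit(data, site, covariates, covariate_names, eb=eb)
    return combat_apply(model, data, site, covariates), model


# ---------------------------------------------------------------------------
# traveling-subject measurement bias
# ---------------------------------------------------------------------------

@dataclass
class SiteBiasTable:
    """Per-site measurement-bias vectors over FC features.

    Satisfies the identifiability constraint that the run-count-weighted
    mean of the site vectors is (numerically) zero.
    """

    sites: np.ndarray
    bias: np.ndarray
    run_counts: np.ndarray

    def for_sites(self, site_labels) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.sites)}
        unseen = sorted({s for s in site_labels if s not in lookup})
        if unseen:
            raise HarmonizeError(f"no bias estimate for site(s) {unseen}")
        return self.bias[[lookup[s] for s in site_labels]]

    def to_tsv(self, path, feature_index=None) -> None:
        cols = (
            [f"ROI{i}_ROI{j}" for i, j in feature_index]
            if feature_index is not None
            else [f"f{k}" for k in range(self.bias.shape[1])]
        )
        pd.DataFrame(self.bias, index=pd.Index(self.sites, name="site"),
                     columns=cols).to_csv(path, sep="\t")


def traveling_bias_estimate(ts: TravelingSubjectSet) -> SiteBiasTable:
    """Estimate per-site measurement bias from traveling-subject runs.

    Fits, per feature, ``value = mu + participant + site + residual`` by
    least squares and returns the site effects re-centred to a
    run-count-weighted zero mean.  Requires every participant to have runs
    at >= 2 sites and a connected participant-site incidence graph
    (otherwise site offsets are not comparable across components).
    """
    labels = ts.labels
    participants, p_idx = np.unique(labels["participant"], return_inverse=True)
    sites, s_idx = np.unique(labels["site"], return_inverse=True)
    n_runs = ts.n_runs

    sites_per_part = (
        pd.DataFrame({"p": p_idx, "s": s_idx}).groupby("p")["s"].nunique()
    )
    lonely = participants[sites_per_part.to_numpy() < 2]
    if lonely.size:
        raise HarmonizeError(
            f"participant(s) {list(lonely)} have runs at fewer than 2 sites"
        )

    # connectivity of the bipartite participant-site graph
    inc = coo_matrix(
        (np.ones(n_runs), (p_idx, s_idx)),
        shape=(participants.size, sites.size),
    )
    adj = coo_matrix(
        np.block([
            [np.zeros((participants.size, participants.size)), inc.toarray()],
            [inc.toarray().T, np.zeros((sites.size, sites.size))],
        ])
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise HarmonizeError(
            "participant-site incidence graph is disconnected; site biases "
            "are not identifiable across components"
        )

    # full-dummy design solved in the least-norm sense, then re-centred
    design = np.zeros((n_runs, 1 + participants.size + sites.size))
    design[:, 0] = 1.0
    design[np.arange(n_runs), 1 + p_idx] = 1.0
    design[np.arange(n_runs), 1 + participants.size + s_idx] = 1.0
    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    site_eff = coef[1 + participants.size:]
    counts = np.bincount(s_idx, minlength=sites.size)
    weighted_mean = (counts / counts.sum()) @ site_eff
    site_eff = site_eff - weighted_mean[None, :]
    return SiteBiasTable(sites=sites, bias=site_eff, run_counts=counts)


def traveling_bias_subtract(data: FCDataset, site,
                            bias: SiteBiasTable) -> FCDataset:
    """Subtract per-site measurement bias from clinical FC data."""
    site = np.asarray(site)
    if bias.bias.shape[1] != data.n_features:
        raise InputError(
            "bias table feature count does not match the dataset"
        )
    corrected = data.values - bias.for_sites(site)
    return FCDataset(corrected, data.feature_index, data.subject_ids)
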