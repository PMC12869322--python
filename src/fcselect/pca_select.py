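"""PCA-based feature selection of functional connections.

The method addresses the p >> n regime of connectome-wide case-control
studies (tens of thousands of FC features, around a thousand subjects):

1. PCA of the subjects x features FC table reduces the feature space to at
   most ``n - 1`` orthogonal components.
2. Each component's per-subject scores are screened for association with
   diagnosis and with nuisance factors (symptom score, age, sex, site,
   head motion) using the test matched to the factor type — two-sample t
   for binary factors, Pearson correlation for continuous ones, one-way
   ANOVA for sites — with Benjamini-Hochberg FDR correction across
   components within each factor.
3. Among the components significant for diagnosis, the one with the
   largest explained variance is the *diagnosis component*; if none is
   significant the procedure returns a null result and selects nothing.
4. The diagnosis component's weights are standardized across features;
   treating them as draws from a normal distribution, features with
   improbably large |weight| (two-tailed, BH-corrected across features at
   ``q = 0.05``) are the selected FCs.

Because selection happens in component space rather than per feature, the
procedure is unsupervised up to the component screen and tends to pick FC
sets whose group differences generalize across cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fc_core import FCDataset, InputError, patient_indicator


@dataclass
class PCModel:
    """Principal components of a centred FC table.

    ``weights`` rows are orthonormal loading vectors (components x
    features) sorted by explained variance; ``scores`` are the per-subject
    projections of the centred data; ``feature_means`` is the centring
    vector needed to project new data.
    """

    weights: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    feature_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]


@dataclass
class SelectionResult:
    """Outcome of one feature-selection method.

    ``positions`` index into the dataset's feature axis; ``direction`` (set
    by :func:`label_direction` or the selector itself) is ``"over"`` when
    the patient-group mean exceeds the control mean on a feature and
    ``"under"`` otherwise.
    """

    method: str
    positions: np.ndarray
    n_features: int
    weights: np.ndarray | None = None
    statistic: np.ndarray | None = None
    direction: np.ndarray | None = None
    q_level: float | None = None
    component: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size != np.unique(self.positions).size:
            raise InputError("selected positions must be unique")
        if self.positions.size and (
            self.positions.min() < 0 or self.positions.max() >= self.n_features
        ):
            raise InputError("selected positions out of feature range")

    @property
    def n_selected(self) -> int:
        return self.positions.size

    def to_dataframe(self, feature_index=None) -> pd.DataFrame:
        out = pd.DataFrame({"position": self.positions})
        if feature_index is not None:
            out["roi_i"] = feature_index[self.positions, 0]
            out["roi_j"] = feature_index[self.positions, 1]
        if self.weights is not None:
            out["weight"] = self.weights
        if self.statistic is not None:
            out["statistic"] = self.statistic
        if self.direction is not None:
            out["direction"] = self.direction
        return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(data: FCDataset | np.ndarray) -> PCModel:
    """PCA of an FC table via SVD of the centred data matrix.

    Features are not standardized (all FCs share the Fisher-z scale).
    Components are sorted by explained variance; the sign of each is fixed
    by requiring its largest-|weight| entry to be positive.  At most
    ``n_subjects - 1`` components are returned (centring removes one
    degree of freedom).
    """
    x = data.values if isinstance(data, FCDataset) else np.asarray(data, float)
    n, m = x.shape
    if n < 3:
        raise InputError("PCA needs at least 3 subjects")
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n - 1, m)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|weight| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s[None, :]
    total = (s ** 2).sum()
    frac = s ** 2 / total if total > 0 else np.zeros(k)
    return PCModel(
        weights=vt,
        scores=scores,
        explained_variance_fraction=frac,
        feature_means=means,
    )


def project_scores(pc: PCModel, component: int,
                   new_data: FCDataset | np.ndarray) -> np.ndarray:
    """Project new subjects onto one fitted component.

    The new data are centred with the *model's* feature means, so scores
    are comparable with the training scores.
    """
    x = new_data.values if isinstance(new_data, FCDataset) else np.asarray(new_data)
    if x.shape[1] != pc.feature_means.size:
        raise InputError(
            f"data have {x.shape[1]} features, model expects "
            f"{pc.feature_means.size}"
        )
    if not 0 <= component < pc.n_components:
        raise InputError(f"component {component} out of range")
    return (x - pc.feature_means[None, :]) @ pc.weights[component]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, adjusted)``: the rejection flags of the step-up
    rule at level ``q`` and the monotone BH-adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    rejected, adjusted = multipletests(p, alpha=q, method="fdr_bh")[:2]
    return rejected, adjusted


# ---------------------------------------------------------------------------
# component screening
# ---------------------------------------------------------------------------

_CONTINUOUS_KINDS = "ifu"


def _factor_test(scores_col: np.ndarray, values: np.ndarray, welch: bool):
    """One factor-association test on one component's scores."""
    finite = pd.notna(values)
    x = scores_col[finite]
    v = values[finite]
    if np.asarray(v).dtype.kind in _CONTINUOUS_KINDS:
        v = np.asarray(v, dtype=float)
        if np.all(v == v[0]):
            raise InputError("continuous factor is constant")
        r, p = stats.pearsonr(x, v)
        return "pearson_r", float(r), float(p)
    levels, level_idx = np.unique(np.asarray(v, dtype=object), return_inverse=True)
    groups = [x[level_idx == g] for g in range(levels.size)]
    if levels.size < 2:
        raise InputError("categorical factor has a single level")
    if levels.size == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
        return "t", float(t), float(p)
    small = [str(levels[g]) for g, grp in enumerate(groups) if grp.size < 2]
    if small:
        raise InputError(f"site/level(s) {small} have fewer than 2 subjects")
    f, p = stats.f_oneway(*groups)
    return "anova_F", float(f), float(p)


def associate(pc: PCModel, pheno: pd.DataFrame, factors,
              q: float = 0.05, welch: bool = False,
              control_label: str = "HC") -> pd.DataFrame:
    """Screen every component against every phenotype factor.

    Binary factors (diagnosis, sex) use a two-sample t-test (pooled by
    default, Welch with ``welch=True``); continuous factors (symptom
    score, age, mean FD) use Pearson correlation with pairwise deletion of
    missing values; multi-level factors (site) use one-way ANOVA.  BH-FDR
    correction is applied across components *within* each factor.

    Returns a tidy table with one row per (factor, component).
    """
    rows = []
    for factor in factors:
        if factor not in pheno.columns:
            raise InputError(f"factor {factor!r} not in phenotype table")
        raw = pheno[factor].to_numpy()
        if factor == "diagnosis":
            # patient/control contrast even when several disorder labels exist
            raw = np.where(
                pheno["diagnosis"].to_numpy() == control_label, "control", "patient"
            )
        stats_p = [
            _factor_test(pc.scores[:, c], raw, welch)
            for c in range(pc.n_components)
        ]
        p_vals = np.array([sp[2] for sp in stats_p])
        rejected, adjusted = bh_fdr(p_vals, q=q)
        for c, (test, statistic, p) in enumerate(stats_p):
            rows.append(
                {
                    "factor": factor,
                    "component": c,
                    "test": test,
                    "statistic": statistic,
                    "p": p,
                    "q": adjusted[c],
                    "significant": bool(rejected[c]),
                }
            )
    return pd.DataFrame(rows)


def choose_diagnosis_pc(assoc: pd.DataFrame, pc: PCModel,
                        factor: str = "diagnosis") -> int | None:
    """Pick the diagnosis component: largest explained variance among the
    components significant for ``factor``; ``None`` when none is (a valid
    null outcome)."""
    sub = assoc[(assoc["factor"] == factor) & assoc["significant"]]
    if sub.empty:
        return None
    comps = sub["component"].to_numpy()
    ev = pc.explained_variance_fraction[comps]
    best = np.flatnonzero(ev == ev.max())
    if best.size > 1:
        warnings.warn(
            "tie in explained variance among significant components; "
            "choosing the lowest component index",
            stacklevel=2,
        )
    return int(comps[best.min()])


# ---------------------------------------------------------------------------
# weight-based feature selection
# ---------------------------------------------------------------------------

def select_features(pc: PCModel, component: int, q: float = 0.05,
                    top_percentile: float | None = None) -> SelectionResult:
    """Extract the FCs with improbably large weights on one component.

    Weights are standardized with their sample mean and SD; two-tailed
    standard-normal probabilities are BH-corrected across all features at
    level ``q`` and the rejected set is selected.  ``top_percentile``
    switches to the *aggressive* variant: select all features whose |z|
    exceeds the given percentile of the |z| distribution, without a
    multiplicity criterion.
    """
    if not 0 <= component < pc.n_components:
        raise InputError(f"component {component} out of range")
    w = pc.weights[component]
    sd = w.std(ddof=1)
    if not np.isfinite(sd) or sd <= np.abs(w).max() * 1e-12:
        raise InputError("degenerate component: all weights equal")
    z = (w - w.mean()) / sd
    if top_percentile is not None:
        cut = np.percentile(np.abs(z), top_percentile)
        positions = np.flatnonzero(np.abs(z) >= cut)
        method = "pca_aggressive"
        q_level = None
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
        rejected, _ = bh_fdr(p, q=q)
        positions = np.flatnonzero(rejected)
        method = "pca"
        q_level = q
    return SelectionResult(
        method=method,
        positions=positions,
        n_features=w.size,
        weights=w[positions],
        statistic=z[positions],
        q_level=q_level,
        component=component,
    )


def label_direction(data: FCDataset, pheno: pd.DataFrame,
                    selection: SelectionResult,
                    control_label: str = "HC") -> SelectionResult:
    """Attach over/under-connectivity labels to a selection.

    ``over`` means the patient-group mean Fisher-z value exceeds the
    control-group mean on that feature; exact ties are labelled ``under``
    with a warning.
    """
    if selection.n_selected == 0:
        raise InputError("cannot label an empty selection")
    y = patient_indicator(pheno, control_label)
    sub = data.values[:, selection.positions]
    diff = sub[y == 1].mean(axis=0) - sub[y == 0].mean(axis=0)
    if np.any(diff == 0):
        warnings.warn(
            "exact group-mean tie on some feature(s); labelling them 'under'",
            stacklevel=2,
        )
    direction = np.where(diff > 0, "over", "under")
    selection.direction = direction
    return selection


def pca_pipeline(data: FCDataset, pheno: pd.DataFrame, q: float = 0.05,
                 factors=("diagnosis",), control_label: str = "HC",
                 top_percentile: float | None = None):
    """Full selection pipeline: PCA, screen, choose component, select, label.

    Returns ``(selection | None, pc_model, association_table)``; the
    selection is ``None`` when no component is significant for diagnosis.
    """
    pc = fit_pca(data)
    assoc = associate(pc, pheno, factors, q=q, control_label=control_label)
    comp = choose_diagnosis_pc(assoc, pc)
    if comp is None:
        return None, pc, assoc
    sel = select_features(pc, comp, q=q, top_percentile=top_percentile)
    if sel.n_selected:
        sel = label_direction(data, pheno, sel, control_label)
    return sel, pc, assoc
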