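"""Comparator feature selectors and the subsampled ensemble classifier.

Two supervised baselines against which the PCA-based selector is judged:

* mass-univariate two-sample t-tests per FC with BH-FDR, Bonferroni, or no
  multiplicity correction;
* stability-style LASSO selection: repeated balanced subsampling, an
  L1-penalized logistic regression per subsample with its penalty chosen
  by internal cross-validation, and selection of the features that are
  non-zero in enough subsamples.

The diagnostic marker is a subsampling ensemble of L1-penalized logistic
members.  Each member draws a balanced subsample, optionally runs a
feature-selection hook *inside* its training subsample (so held-out rows
never influence feature choice — the no-leakage contract), fits on the
selected columns, and the ensemble averages member probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score

from .fc_core import FCDataset, InputError
from .pca_select import SelectionResult, bh_fdr, fit_pca, select_features

logger = logging.getLogger(__name__)

DEFAULT_CS = (0.01, 0.0316, 0.1, 0.316, 1.0)


def _as_values(data) -> np.ndarray:
    return data.values if isinstance(data, FCDataset) else np.asarray(data, float)


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2 or set(classes) != {0, 1}:
        raise InputError("labels must contain both classes coded 0/1")
    return y


# ---------------------------------------------------------------------------
# univariate t-test selector
# ---------------------------------------------------------------------------

def ttest_select(data, labels, correction: str = "fdr_bh",
                 alpha: float = 0.05) -> SelectionResult:
    """Mass-univariate two-sample t-test selection.

    ``correction`` is ``"fdr_bh"``, ``"bonferroni"``, or ``"none"``.
    Direction labels come from the sign of the patient-minus-control mean
    difference.
    """
    x = _as_values(data)
    y = _check_binary(labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise InputError("both groups need at least 2 subjects")
    t, p = stats.ttest_ind(x[y == 1], x[y == 0], axis=0)
    if correction == "fdr_bh":
        rejected, _ = bh_fdr(p, q=alpha)
    elif correction == "bonferroni":
        rejected = p <= alpha / p.size
    elif correction == "none":
        rejected = p <= alpha
    else:
        raise InputError(f"unknown correction {correction!r}")
    positions = np.flatnonzero(rejected)
    return SelectionResult(
        method=f"ttest_{correction}",
        positions=positions,
        n_features=x.shape[1],
        statistic=t[positions],
        direction=np.where(t[positions] > 0, "over", "under"),
        q_level=alpha,
    )


# ---------------------------------------------------------------------------
# subsampled LASSO selector
# ---------------------------------------------------------------------------

def _balanced_subsample(y: np.ndarray, rng: np.random.Generator,
                        fraction: float) -> np.ndarray:
    """Row indices of a balanced subsample (equal group counts)."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    per_group = max(int(round(fraction * min(idx0.size, idx1.size))), 2)
    take0 = rng.choice(idx0, size=per_group, replace=False)
    take1 = rng.choice(idx1, size=per_group, replace=False)
    return np.concatenate([take0, take1])


def _member_fit(x, y, Cs, cv, random_state) -> LogisticRegressionCV:
    clf = LogisticRegressionCV(
        Cs=list(Cs), cv=cv, penalty="l1", solver="liblinear",
        scoring="roc_auc", max_iter=2000, random_state=random_state,
        refit=True,
    )
    with warnings.catch_warnings():
        # scikit-learn >= 1.8 deprecation chatter about the future
        # l1_ratios/attribute API; the l1 fit itself is unchanged
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(x, y)
    return clf


def lasso_select(data, labels, n_subsamples: int = 100,
                 selection_count_threshold: int | None = None,
                 Cs=DEFAULT_CS, cv: int = 10,
                 subsample_fraction: float = 0.8,
                 random_state: int = 0) -> SelectionResult:
    """LASSO-based feature selection with repeated balanced subsampling.

    Each subsample draws equal numbers of patients and controls
    (undersampling the majority class); an L1-penalized logistic model is
    fitted with its penalty chosen by ``cv``-fold cross-validation over
    ``Cs``; a feature is selected when its coefficient is non-zero in at
    least ``selection_count_threshold`` subsamples (default: half of
    them, rounded up).
    """
    x = _as_values(data)
    y = _check_binary(labels)
    if n_subsamples > 1 and ((y == 1).sum() < 10 or (y == 0).sum() < 10):
        raise InputError("both groups need >= 10 subjects for subsampled LASSO")
    if selection_count_threshold is None:
        selection_count_threshold = int(np.ceil(n_subsamples / 2))
    rng = np.random.default_rng(random_state)
    counts = np.zeros(x.shape[1], dtype=int)
    coef_sum = np.zeros(x.shape[1])
    for s in range(n_subsamples):
        rows = (
            np.arange(y.size) if n_subsamples == 1 and subsample_fraction >= 1.0
            else _balanced_subsample(y, rng, subsample_fraction)
        )
        clf = _member_fit(x[rows], y[rows], Cs, cv, random_state + s)
        nz = clf.coef_.ravel() != 0
        counts += nz
        coef_sum += clf.coef_.ravel()
    positions = np.flatnonzero(counts >= selection_count_threshold)
    mean_coef = coef_sum[positions] / n_subsamples
    return SelectionResult(
        method="lasso",
        positions=positions,
        n_features=x.shape[1],
        weights=mean_coef,
        statistic=counts[positions].astype(float),
        direction=np.where(mean_coef > 0, "over", "under"),
        meta={"n_subsamples": n_subsamples,
              "threshold": selection_count_threshold},
    )


# ---------------------------------------------------------------------------
# ensemble classifier
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    positions: np.ndarray
    classifier: LogisticRegressionCV
    train_rows: np.ndarray


@dataclass
class EnsembleModel:
    """Subsampling ensemble of L1-penalized logistic members.

    Member probabilities are averaged; ``scores`` returns the mean
    patient probability per subject.
    """

    members: list[EnsembleMember]
    n_features: int
    aggregation: str = "mean_proba"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise InputError("ensemble needs at least 1 member")

    @property
    def mean_selected(self) -> float:
        """Average selected-feature count across members (the per-member
        training dimensionality)."""
        return float(np.mean([m.positions.size for m in self.members]))

    def scores(self, data) -> np.ndarray:
        x = _as_values(data)
        if x.shape[1] != self.n_features:
            raise InputError("feature count does not match the ensemble")
        probs = [
            m.classifier.predict_proba(x[:, m.positions])[:, 1]
            for m in self.members
        ]
        return np.mean(probs, axis=0)


def pca_inner_selector(q: float = 0.05, top_percentile: float | None = None,
                       control_label: str = "HC"):
    """Feature-selection hook running the PCA method inside a training fold.

    The hook receives the member's training matrix and labels only, so PCA
    weights are estimated without the held-out rows.  Falls back to the
    first component when no component is diagnosis-significant (members
    must produce some feature set to fit on).
    """
    from .pca_select import associate as _associate, choose_diagnosis_pc
    import pandas as pd

    def selector(x_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
        pc = fit_pca(x_train)
        pheno = pd.DataFrame(
            {"diagnosis": np.where(y_train == 1, "patient", control_label)}
        )
        assoc = _associate(pc, pheno, ["diagnosis"], q=q,
                           control_label=control_label)
        comp = choose_diagnosis_pc(assoc, pc)
        if comp is None:
            return np.array([], dtype=np.int64)
        sel = select_features(pc, comp, q=q, top_percentile=top_percentile)
        return sel.positions

    return selector


def ttest_inner_selector(correction: str = "fdr_bh", alpha: float = 0.05):
    """t-test feature-selection hook for in-fold use."""

    def selector(x_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
        return ttest_select(x_train, y_train, correction, alpha).positions

    return selector


def ensemble_fit(data, labels, n_subsamples: int = 100,
                 inner_selector=None, Cs=DEFAULT_CS, cv: int = 10,
                 subsample_fraction: float = 0.8,
                 random_state: int = 0) -> EnsembleModel:
    """Fit the subsampling ensemble-LASSO diagnostic marker.

    When ``inner_selector`` is given it is called with each member's
    training matrix and labels *before* the member fit; an empty returned
    set makes the member fall back to all features (logged).
    """
    x = _as_values(data)
    y = _check_binary(labels)
    rng = np.random.default_rng(random_state)
    members = []
    for s in range(n_subsamples):
        rows = (
            np.arange(y.size) if n_subsamples == 1 and subsample_fraction >= 1.0
            else _balanced_subsample(y, rng, subsample_fraction)
        )
        x_tr, y_tr = x[rows], y[rows]
        if inner_selector is not None:
            positions = np.asarray(inner_selector(x_tr, y_tr), dtype=np.int64)
            if positions.size == 0:
                logger.info(
                    "member %d: selector returned no features; "
                    "falling back to all features", s,
                )
                positions = np.arange(x.shape[1], dtype=np.int64)
        else:
            positions = np.arange(x.shape[1], dtype=np.int64)
        clf = _member_fit(x_tr[:, positions], y_tr, Cs, cv, random_state + s)
        members.append(EnsembleMember(positions, clf, rows))
    return EnsembleModel(
        members=members, n_features=x.shape[1],
        meta={"n_subsamples": n_subsamples, "cv": cv, "Cs": tuple(Cs)},
    )


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc, "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity, "Specificity": self.specificity,
            "MCC": self.mcc,
        }


def _mcc(tp, fp, tn, fn) -> float:
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def evaluate_classifier(model: EnsembleModel, data, labels,
                        threshold: float = 0.5) -> ClassifierMetrics:
    """Test-set metrics: rank-based AUC plus confusion-matrix rates and MCC."""
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise InputError("AUC is undefined for one-class test labels")
    scores = model.scores(data)
    auc = float(roc_auc_score(y, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ClassifierMetrics(
        auc=auc,
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        mcc=_mcc(tp, fp, tn, fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
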