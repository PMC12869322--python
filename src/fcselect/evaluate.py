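"""Effect sizes, selection robustness, and variance decomposition.

Tools for judging how well a selected FC set generalizes:

* Hedge's g per feature (standardized patient-minus-control mean
  difference with the small-sample correction ``J = 1 - 3/(4N - 9)``),
  and per-method summaries of |g| in discovery vs validation cohorts;
* overlap between two selections on the same feature space;
* Pearson correlation of per-feature g vectors across cohorts
  (cross-dataset consistency);
* traveling-subject variance decomposition: per FC, the variability
  attributable to participant, scanner, protocol, and session factors
  under an additive model, and Wilcoxon rank-sum comparisons of those
  variabilities between selected FC sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fc_core import FCDataset, InputError, TravelingSubjectSet
from .pca_select import SelectionResult

FACTORS = ("participant", "scanner", "session", "protocol")


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def hedges_g(data, labels, unbiased: bool = True) -> np.ndarray:
    """Per-feature Hedge's g, patient (1) minus control (0).

    ``unbiased=False`` drops the small-sample correction factor J and
    returns Cohen's d.  Features with zero pooled SD come back as NaN.
    """
    x = data.values if isinstance(data, FCDataset) else np.asarray(data, float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise InputError("both groups need at least 2 subjects")
    x1, x0 = x[y == 1], x[y == 0]
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    s2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n0 - 1) * x0.var(axis=0, ddof=1))
    s_pooled = np.sqrt(s2 / (n1 + n0 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        g = diff / s_pooled
    g[s_pooled == 0] = np.nan
    if unbiased:
        g = g * (1.0 - 3.0 / (4.0 * (n1 + n0) - 9.0))
    return g


def effect_summary(g_tables: dict[str, np.ndarray],
                   selections, absolute: bool = True) -> pd.DataFrame:
    """Per-method mean/median/SD of effect sizes over selected features.

    ``g_tables`` maps dataset names (e.g. ``discovery`` / ``validation``)
    to per-feature g vectors on a shared feature space; ``selections`` is
    a list of :class:`SelectionResult`.  Summaries are over |g| by default
    (selections mix over- and under-connectivity); pass ``absolute=False``
    for signed summaries.  NaN effect sizes (degenerate features) are
    excluded.  Empty selections produce a null row with a warning.
    """
    rows = []
    for sel in selections:
        for name, g in g_tables.items():
            g = np.asarray(g, dtype=float)
            if sel.n_selected == 0:
                warnings.warn(
                    f"selection {sel.method!r} is empty; emitting null row",
                    stacklevel=2,
                )
                rows.append({"method": sel.method, "dataset": name,
                             "n_selected": 0, "mean": np.nan, "median": np.nan,
                             "sd": np.nan})
                continue
            vals = g[sel.positions]
            vals = vals[np.isfinite(vals)]
            if absolute:
                vals = np.abs(vals)
            rows.append(
                {
                    "method": sel.method,
                    "dataset": name,
                    "n_selected": sel.n_selected,
                    "mean": vals.mean(),
                    "median": float(np.median(vals)),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def selection_overlap(a: SelectionResult,
                      b: SelectionResult) -> tuple[int, np.ndarray]:
    """Intersection of two selections by feature position."""
    if a.n_features != b.n_features:
        raise InputError(
            f"selections live on different feature spaces "
            f"({a.n_features} vs {b.n_features})"
        )
    common = np.intersect1d(a.positions, b.positions)
    return int(common.size), common


def cross_dataset_consistency(g_discovery, g_validation) -> float:
    """Pearson r between discovery and validation per-feature g vectors."""
    g1 = np.asarray(g_discovery, dtype=float)
    g2 = np.asarray(g_validation, dtype=float)
    if g1.shape != g2.shape:
        raise InputError("effect-size vectors must share the feature space")
    finite = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[finite], g2[finite]
    if np.all(g1 == g1[0]) or np.all(g2 == g2[0]):
        raise InputError("constant effect-size vector: correlation undefined")
    return float(stats.pearsonr(g1, g2)[0])


# ---------------------------------------------------------------------------
# traveling-subject variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class FactorVariability:
    """Per-feature, per-factor variability of FC values.

    ``table`` has one row per FC feature and one column per factor in
    :data:`FACTORS`.  Participant/scanner/protocol variability is the SD
    of the corresponding fitted sum-to-zero level effects; session
    variability is the residual SD of the additive model.
    """

    table: pd.DataFrame
    meta: dict

    def __getitem__(self, factor: str) -> np.ndarray:
        return self.table[factor].to_numpy()

    def summary(self) -> pd.DataFrame:
        return self.table.agg(["mean", "std"]).T


def _effect_coding(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Sum-to-zero (effect) coding; returns (columns, levels, n_levels)."""
    levels, idx = np.unique(labels, return_inverse=True)
    k = levels.size
    if k == 1:
        return np.empty((labels.size, 0)), levels, 1
    cols = np.zeros((labels.size, k - 1))
    for lv in range(k - 1):
        cols[idx == lv, lv] = 1.0
    cols[idx == k - 1, :] = -1.0
    return cols, levels, k


def factor_variability(ts: TravelingSubjectSet) -> FactorVariability:
    """Decompose per-FC variability into participant / scanner / session /
    protocol contributions.

    Fits, per feature, the additive model ``value = grand mean +
    participant + scanner + protocol + residual`` by least squares with
    sum-to-zero constraints; the variability of a fitted factor is the
    sample SD of its level effects, and the session factor is the
    residual SD.  A factor with a single level contributes 0 with a
    warning.
    """
    labels = ts.labels
    blocks = []
    spans = {}
    col = 1
    level_counts = {}
    for factor in ("participant", "scanner", "protocol"):
        cols, levels, k = _effect_coding(labels[factor].to_numpy())
        level_counts[factor] = k
        if k == 1:
            warnings.warn(
                f"factor {factor!r} has a single level; its variability is 0",
                stacklevel=2,
            )
        blocks.append(cols)
        spans[factor] = (col, col + cols.shape[1])
        col += cols.shape[1]
    design = np.hstack([np.ones((ts.n_runs, 1))] + blocks)
    rank = np.linalg.matrix_rank(design)
    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ coef
    dof = max(ts.n_runs - rank, 1)
    session_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)

    out = {}
    for factor in ("participant", "scanner", "protocol"):
        lo, hi = spans[factor]
        k = level_counts[factor]
        if k == 1:
            out[factor] = np.zeros(ts.n_features)
            continue
        partial = coef[lo:hi]
        full = np.vstack([partial, -partial.sum(axis=0, keepdims=True)])
        out[factor] = full.std(axis=0, ddof=1)
    out["session"] = session_sd
    table = pd.DataFrame({f: out[f] for f in FACTORS})
    return FactorVariability(
        table=table,
        meta={
            "model": "additive least squares, sum-to-zero constraints",
            "note": (
                "factor variability approximated as the SD of fitted level "
                "effects; session is the run-level residual SD"
            ),
            "n_runs": ts.n_runs,
            "rank": int(rank),
        },
    )


def variability_compare(fv: FactorVariability, selections,
                        min_selected: int = 3) -> pd.DataFrame:
    """Compare factor variability between selected FC sets.

    For every pair of selections and every factor, a two-sided Wilcoxon
    rank-sum (Mann-Whitney) test compares the per-feature variability
    distributions.  Selections smaller than ``min_selected`` are skipped
    with a warning.  Returns a tidy table of pairwise results together
    with per-selection mean variability.
    """
    usable = []
    for sel in selections:
        if sel.n_selected < min_selected:
            warnings.warn(
                f"selection {sel.method!r} has fewer than {min_selected} "
                "features; skipping its comparisons",
                stacklevel=2,
            )
        else:
            usable.append(sel)
    rows = []
    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            a, b = usable[ai], usable[bi]
            for factor in FACTORS:
                va = fv[factor][a.positions]
                vb = fv[factor][b.positions]
                u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
                rows.append(
                    {
                        "factor": factor,
                        "method_a": a.method,
                        "method_b": b.method,
                        "mean_a": va.mean(),
                        "mean_b": vb.mean(),
                        "U": float(u),
                        "p": float(p),
                    }
                )
    return pd.DataFrame(rows)
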