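"""Functional-connectivity data model and FC-vector construction.

A functional connection (FC) is the Fisher-z-transformed Pearson correlation
between the resting-state signal time courses of two brain regions (ROIs).
With ``R`` regions there are ``R*(R-1)/2`` FCs, one per unordered region
pair; a subject is represented by the vector of all of them.

This module holds the in-memory containers shared across the package
(:class:`ROIRun`, :class:`FCDataset`, :class:`TravelingSubjectSet`, and the
phenotype table conventions) together with the time-series processing chain
used to build FC vectors: nuisance regression, band-pass filtering,
motion scrubbing, run-exclusion rules, correlation + Fisher z, and the
lower-triangle vectorization convention.

Conventions
-----------
* Region labels are 1-based in all I/O and in ``feature_index``; internal
  array indices are 0-based.
* Feature order is column-major over the strict lower triangle of the
  connectivity matrix: ``(2,1), (3,1), ..., (R,1), (3,2), (4,2), ...``
  (pairs written ``(i, j)`` with ``i > j``).
* Phenotype tables are plain :class:`pandas.DataFrame` objects with columns
  ``subject_id, diagnosis, site, age, sex, symptom_score, mean_fd``;
  ``symptom_score`` may contain missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal


class InputError(ValueError):
    """Invalid input shape, value, or label."""


class EmptyRunError(InputError):
    """Every frame of a run was censored; the run must be excluded."""


PHENOTYPE_COLUMNS = (
    "subject_id",
    "diagnosis",
    "site",
    "age",
    "sex",
    "symptom_score",
    "mean_fd",
)


# ---------------------------------------------------------------------------
# pair <-> position bijection
# ---------------------------------------------------------------------------

def n_pairs(n_rois: int) -> int:
    """Number of FC features for ``n_rois`` regions (strict lower triangle)."""
    if n_rois < 2:
        raise InputError(f"need at least 2 regions, got {n_rois}")
    return n_rois * (n_rois - 1) // 2


def pair_index(i, j, n_rois: int):
    """Feature position of region pair ``(i, j)`` with ``i > j`` (1-based).

    Vectorized over ``i`` and ``j``. The mapping is column-major over the
    strict lower triangle, so positions run ``(2,1)=0, (3,1)=1, ...``.
    """
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(j < 1) or np.any(i > n_rois) or np.any(i <= j):
        raise InputError("region pair must satisfy 1 <= j < i <= n_rois")
    offset = (j - 1) * (2 * n_rois - j) // 2
    pos = offset + (i - j - 1)
    return pos if pos.ndim else int(pos)


def inverse_pair_index(position, n_rois: int):
    """Region pair ``(i, j)`` (1-based, ``i > j``) at a feature position."""
    pos = np.asarray(position, dtype=np.int64)
    m = n_pairs(n_rois)
    if np.any(pos < 0) or np.any(pos >= m):
        raise InputError(f"position out of range [0, {m})")
    # cum[k] = number of features in columns 1..k+1
    cum = np.cumsum(np.arange(n_rois - 1, 0, -1))
    jm1 = np.searchsorted(cum, pos, side="right")
    j = jm1 + 1
    offset = (j - 1) * (2 * n_rois - j) // 2
    i = j + 1 + (pos - offset)
    if pos.ndim:
        return i, j
    return int(i), int(j)


def all_pairs(n_rois: int) -> np.ndarray:
    """``(m, 2)`` array of 1-based region pairs ``(i, j)`` in feature order."""
    r, c = np.triu_indices(n_rois, k=1)
    # upper-triangle row-major (r < c) visits the lower triangle (i=c+1, j=r+1)
    # in exactly the column-major order of this package's convention
    return np.column_stack([c + 1, r + 1]).astype(np.int64)


def synthetic_pairs(n_features: int) -> np.ndarray:
    """A valid ``feature_index`` for an arbitrary feature count.

    Uses the smallest region count whose lower triangle holds ``n_features``
    pairs and takes the first ``n_features`` of them.  Intended for synthetic
    datasets whose features do not come from a real parcellation.
    """
    n_rois = int(np.ceil((1 + np.sqrt(1 + 8 * n_features)) / 2))
    return all_pairs(n_rois)[:n_features]


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Lower-triangle vector of a symmetric zero-diagonal matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InputError("connectivity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise InputError("connectivity matrix must be symmetric")
    r, c = np.triu_indices(mat.shape[0], k=1)
    return mat[r, c].copy()


def matrixize_vector(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Symmetric zero-diagonal matrix from a lower-triangle feature vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_pairs(n_rois):
        raise InputError(
            f"vector length {vec.size} does not match {n_pairs(n_rois)} pairs"
        )
    mat = np.zeros((n_rois, n_rois))
    r, c = np.triu_indices(n_rois, k=1)
    mat[r, c] = vec
    mat[c, r] = vec
    return mat


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ROIRun:
    """One resting-state run: frames x regions signal with motion series.

    Parameters
    ----------
    signal:
        Real matrix, frames x regions.
    tr_seconds:
        Sampling interval (repetition time) in seconds.
    fd:
        Per-frame framewise displacement in millimetres; the first frame is
        0 by definition.  Length must equal the frame count.
    """

    signal: np.ndarray
    tr_seconds: float
    fd: np.ndarray
    run_id: str = "run"
    subject_id: str = "subject"
    site_id: str = "site"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.signal.ndim != 2:
            raise InputError("signal must be a frames x regions matrix")
        if self.signal.shape[0] < 2:
            raise InputError("run must have at least 2 frames")
        if self.fd.shape != (self.signal.shape[0],):
            raise InputError(
                f"fd length {self.fd.size} != frame count {self.signal.shape[0]}"
            )
        if not np.isfinite(self.signal).all() or not np.isfinite(self.fd).all():
            raise InputError("signal and fd must be finite")
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signal.shape[1]


@dataclass
class FCDataset:
    """Subjects x FC-features matrix of Fisher-z values.

    ``feature_index`` is the ordered ``(m, 2)`` list of 1-based region pairs
    ``(i, j)``, ``i > j``, defining what each column measures.
    """

    values: np.ndarray
    feature_index: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_index = np.asarray(self.feature_index, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise InputError("values must be subjects x features")
        if self.feature_index.shape != (self.values.shape[1], 2):
            raise InputError("feature_index must be (n_features, 2)")
        if not np.isfinite(self.values).all():
            raise InputError("FC values must be finite")
        i, j = self.feature_index[:, 0], self.feature_index[:, 1]
        if np.any(i <= j):
            raise InputError("feature_index pairs must satisfy i > j")
        if len({(a, b) for a, b in self.feature_index}) != len(self.feature_index):
            raise InputError("feature_index contains duplicate pairs")
        if self.subject_ids.shape != (self.values.shape[0],):
            raise InputError("subject_ids length must match subject count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"ROI{i}_ROI{j}" for i, j in self.feature_index]

    def subset_subjects(self, mask) -> "FCDataset":
        mask = np.asarray(mask)
        return FCDataset(self.values[mask], self.feature_index, self.subject_ids[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_names,
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FCDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = _parse_pair_names(df.columns)
        return cls(df.to_numpy(float), pairs, df.index.to_numpy())


def _parse_pair_names(names) -> np.ndarray:
    pairs = []
    for name in names:
        try:
            a, b = name.split("_")
            pairs.append((int(a[3:]), int(b[3:])))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise InputError(f"cannot parse FC column name {name!r}") from exc
    return np.asarray(pairs, dtype=np.int64)


@dataclass
class TravelingSubjectSet:
    """Runs x FC-features matrix from a traveling-subject design.

    Each run carries participant / site / scanner / protocol / session
    labels in ``labels`` (one row per run, aligned with ``values``).
    """

    values: np.ndarray
    labels: pd.DataFrame
    feature_index: np.ndarray

    REQUIRED = ("run_id", "participant", "site", "scanner", "protocol", "session")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_index = np.asarray(self.feature_index, dtype=np.int64)
        missing = [c for c in self.REQUIRED if c not in self.labels.columns]
        if missing:
            raise InputError(f"labels table is missing columns {missing}")
        if len(self.labels) != self.values.shape[0]:
            raise InputError("labels must have one row per run")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def validate_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract and return the table unchanged."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise InputError(f"phenotype table is missing columns {missing}")
    if pheno["subject_id"].duplicated().any():
        raise InputError("subject_id values must be unique")
    if pheno["diagnosis"].isna().any() or pheno["site"].isna().any():
        raise InputError("diagnosis and site must be non-missing")
    return pheno


def patient_indicator(pheno: pd.DataFrame, control_label: str = "HC") -> np.ndarray:
    """Binary patient (1) / control (0) labels from the diagnosis column."""
    return (pheno["diagnosis"].to_numpy() != control_label).astype(int)


# ---------------------------------------------------------------------------
# time-series processing
# ---------------------------------------------------------------------------

def regress_nuisance(run: ROIRun, regressors: np.ndarray) -> ROIRun:
    """Remove nuisance variance by linear regression.

    An intercept column is always added, so the residuals are orthogonal to
    the span of the supplied regressors plus the constant.  Rank-deficient
    designs are solved in the least-norm sense with a warning.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != run.n_frames:
        raise InputError(
            f"regressors have {regressors.shape[0]} rows, run has {run.n_frames} frames"
        )
    design = np.column_stack([np.ones(run.n_frames), regressors])
    beta, _, rank, _ = np.linalg.lstsq(design, run.signal, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "nuisance design is rank deficient; using least-norm solution",
            stacklevel=2,
        )
    residual = run.signal - design @ beta
    return replace(run, signal=residual, fd=run.fd.copy())


def bandpass(run: ROIRun, low_hz: float = 0.01, high_hz: float = 0.08,
             order: int = 1) -> ROIRun:
    """Zero-phase Butterworth band-pass filter along the time axis.

    Defaults restrict the signal to the 0.01-0.08 Hz band of slow
    resting-state fluctuations.  The filter is applied forward-backward
    (``filtfilt``) so the output is shift invariant.
    """
    fs = 1.0 / run.tr_seconds
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise InputError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise InputError(
            f"high cutoff {high_hz} Hz is not below the Nyquist rate "
            f"{nyquist} Hz for tr={run.tr_seconds}s"
        )
    b, a = _signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)
    filtered = _signal.filtfilt(b, a, run.signal, axis=0)
    return replace(run, signal=filtered, fd=run.fd.copy())


def scrub(run: ROIRun, fd_threshold_mm: float = 0.5) -> tuple[ROIRun, float]:
    """Remove high-motion frames (FD strictly above threshold).

    Returns the censored run and the censored fraction.  Raises
    :class:`EmptyRunError` when no frame survives.
    """
    if fd_threshold_mm <= 0:
        raise InputError("fd threshold must be positive")
    keep = run.fd <= fd_threshold_mm
    frac = 1.0 - keep.mean()
    if not keep.any():
        raise EmptyRunError(
            f"all {run.n_frames} frames of run {run.run_id!r} exceed "
            f"FD {fd_threshold_mm} mm"
        )
    if keep.sum() < 2:
        raise EmptyRunError(
            f"fewer than 2 frames of run {run.run_id!r} survive scrubbing"
        )
    return replace(run, signal=run.signal[keep], fd=run.fd[keep]), float(frac)


def exclusion_flags(censored_fractions, mode: str, *, tr_seconds: float | None = None,
                    min_minutes: float = 4.0,
                    retained_frames=None) -> np.ndarray:
    """Per-run keep (True) / exclude (False) flags.

    ``mode="mean3sd"`` excludes runs whose censored fraction strictly
    exceeds the mean + 3 x sample SD of all runs' fractions.
    ``mode="min_duration"`` excludes runs whose retained data span
    (``retained_frames * tr_seconds``) falls below ``min_minutes``.
    """
    fractions = np.asarray(censored_fractions, dtype=float)
    if mode == "mean3sd":
        if fractions.size < 2:
            raise InputError("mean3sd mode needs at least 2 runs")
        sd = fractions.std(ddof=1)
        return fractions <= fractions.mean() + 3.0 * sd
    if mode == "min_duration":
        if tr_seconds is None or retained_frames is None:
            raise InputError(
                "min_duration mode needs tr_seconds and retained_frames"
            )
        retained = np.asarray(retained_frames, dtype=float)
        return retained * tr_seconds >= min_minutes * 60.0
    raise InputError(f"unknown exclusion mode {mode!r}")


def fc_vector(run: ROIRun, tolerant: bool = False) -> np.ndarray:
    """FC feature vector of one run: Fisher z of all pairwise correlations.

    With ``tolerant=True`` correlations are clipped to ``+/-(1 - 1e-7)``
    before the z-transform; by default a correlation of exactly ``+/-1``
    is an error because it signals degenerate input.
    """
    if run.n_frames < 3:
        raise InputError("need at least 3 retained frames to correlate")
    sd = run.signal.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise InputError(
            f"zero-variance region(s) {[int(d) + 1 for d in dead]} in run "
            f"{run.run_id!r}"
        )
    corr = np.corrcoef(run.signal, rowvar=False)
    r_idx, c_idx = np.triu_indices(run.n_regions, k=1)
    r = corr[r_idx, c_idx]
    limit = 1.0 - 1e-7
    if tolerant:
        r = np.clip(r, -limit, limit)
    elif np.any(np.abs(r) >= 1.0 - 1e-12):
        k = int(np.flatnonzero(np.abs(r) >= 1.0 - 1e-12)[0])
        raise InputError(
            f"|r| = 1 for region pair ({c_idx[k] + 1}, {r_idx[k] + 1}); "
            "Fisher z is infinite (pass tolerant=True to clip)"
        )
    return np.arctanh(r)


def dataset_from_runs(runs, tolerant: bool = False) -> FCDataset:
    """Stack per-run FC vectors into an :class:`FCDataset` (one row per run)."""
    runs = list(runs)
    if not runs:
        raise InputError("no runs given")
    n_regions = runs[0].n_regions
    if any(r.n_regions != n_regions for r in runs):
        raise InputError("all runs must share the region count")
    values = np.vstack([fc_vector(r, tolerant=tolerant) for r in runs])
    ids = np.asarray([r.subject_id for r in runs])
    return FCDataset(values, all_pairs(n_regions), ids)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_timeseries(path, tr_seconds: float, fd_path=None, **labels) -> ROIRun:
    """Load a frames x regions delimited-text time series (+ optional FD file)."""
    df = pd.read_csv(path, sep="\t")
    signal = df.to_numpy(float)
    if fd_path is not None:
        fd = pd.read_csv(fd_path, sep="\t", header=None).to_numpy(float).ravel()
    else:
        fd = np.zeros(signal.shape[0])
    return ROIRun(signal=signal, tr_seconds=tr_seconds, fd=fd, **labels)


def write_timeseries(path, run: ROIRun) -> None:
    cols = [f"ROI{k + 1}" for k in range(run.n_regions)]
    pd.DataFrame(run.signal, columns=cols).to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    return validate_phenotype(pd.read_csv(path, sep="\t"))


def write_phenotype(path, pheno: pd.DataFrame) -> None:
    validate_phenotype(pheno).to_csv(path, sep="\t", index=False)
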