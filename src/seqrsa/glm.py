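"""First-level GLM: event relabeling, design construction and t-maps.

Three labeling schemes turn the same 120 events per run into three GLMs:

* ``position`` — label = temporal position in the stream (1-8),
* ``key``      — label = key pressed (1-8),
* ``object``   — label = canonical object index (1-8).

Because item and position are locked together in the sequence conditions,
those events form the same partition under every scheme; only the random
condition's events regroup.  Each run yields 8 labels x 3 conditions = 24
interest regressors (5 events each), i.e. 192 across the 8 runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf
from scipy.signal import fftconvolve

from .protocol import CONDITIONS, N_POSITIONS
from .tmaps import OBJECT_INDEX, SCHEMES, TMapSet

HIGHPASS_CUTOFF_S = 128.0

#: temporal oversampling of the HRF grid (shared with the BOLD simulator so
#: that a noiseless simulation is exactly within the GLM's model class)
HRF_OVERSAMPLE = 16


def hrf_convolve_impulses(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    tr: float,
    n_scans: int,
) -> np.ndarray:
    """Delta functions at ``onsets`` convolved with the canonical HRF.

    ``amplitudes`` is (n_events,) for a design column or (n_events, k) for
    multi-channel (e.g. per-voxel) output; returns (n_scans,) or
    (n_scans, k) sampled at multiples of ``tr``.  Onsets snap to a grid of
    ``tr / 16``; the double-gamma kernel has the standard shape (peak 6 s,
    undershoot 16 s, ratio 1:6).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    squeeze = amplitudes.ndim == 1
    amp = amplitudes[:, None] if squeeze else amplitudes
    dt = tr / HRF_OVERSAMPLE
    n_grid = n_scans * HRF_OVERSAMPLE
    impulses = np.zeros((n_grid, amp.shape[1]))
    idx = np.rint(np.asarray(onsets, dtype=float) / dt).astype(int)
    if np.any(idx >= n_grid):
        raise ValueError("event onset beyond run end")
    np.add.at(impulses, idx, amp)
    kernel = spm_hrf(tr, oversampling=HRF_OVERSAMPLE)
    series = fftconvolve(impulses, kernel[:, None], axes=0)[:n_grid]
    series = series[::HRF_OVERSAMPLE]
    return series[:, 0] if squeeze else series


def relabel_events(events: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Attach a regressor ``label`` (1-8) to each event under a scheme.

    Sequence-condition events keep one fixed partition (by stream position,
    the learned slot) under all three schemes; the label is the domain item
    at that slot where the scheme matches the condition's domain (key for
    SQ_MOT, object for SQ_OBJ) and the slot index otherwise.  Random events
    regroup by the scheme's attribute.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    required = {"condition", "position", "key", "object"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing field(s) {sorted(missing)}")
    out = events.copy()
    position = out["position"].to_numpy()
    key = out["key"].to_numpy()
    obj_idx = out["object"].map(OBJECT_INDEX).to_numpy()
    cond = out["condition"].to_numpy()
    if scheme == "position":
        label = position.copy()
    elif scheme == "key":
        label = np.where(cond == "SQ_OBJ", position, key)
    else:
        label = np.where(cond == "SQ_MOT", position, obj_idx)
    out["label"] = label.astype(int)
    return out


@dataclass
class DesignMatrix:
    """Sampled design for one run: interest, nuisance and drift columns."""

    matrix: np.ndarray            # (n_scans, n_columns)
    columns: list[str]
    n_interest: int
    frame_times: np.ndarray

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


def cosine_drift_basis(frame_times: np.ndarray,
                       cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """DCT-II high-pass basis (plus constant) for the given cutoff period."""
    n = len(frame_times)
    duration = frame_times[-1] - frame_times[0]
    order = max(int(np.floor(2 * duration / cutoff_s)), 0)
    t = np.arange(n)
    basis = [np.ones(n) / np.sqrt(n)]
    for k in range(1, order + 1):
        basis.append(np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    return np.column_stack(basis)


def build_design(
    labeled_events: pd.DataFrame,
    tr: float,
    n_scans: int,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
    highpass_cutoff_s: float = HIGHPASS_CUTOFF_S,
) -> DesignMatrix:
    """Build one run's design matrix from relabeled events.

    Events of interest enter as delta functions (0 s duration) at cue onset,
    convolved with the canonical double-gamma HRF.  Columns are ordered
    (condition, label); a cosine drift set implements the high-pass filter.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    frame_times = np.arange(n_scans) * tr
    run_end = n_scans * tr
    if (labeled_events["onset_s"] >= run_end).any():
        bad = labeled_events.loc[labeled_events["onset_s"] >= run_end, "onset_s"].iloc[0]
        raise ValueError(f"event onset {bad:.1f}s beyond run end {run_end:.1f}s")
    cols, names = [], []
    for condition in CONDITIONS:
        for label in range(1, N_POSITIONS + 1):
            sel = labeled_events[
                (labeled_events["condition"] == condition)
                & (labeled_events["label"] == label)
            ]
            onsets = sel["onset_s"].to_numpy(dtype=float)
            cols.append(hrf_convolve_impulses(
                onsets, np.ones_like(onsets), tr, n_scans))
            names.append(f"{condition}/{label}")
    n_interest = len(cols)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(
                nuisance_names[j] if nuisance_names else f"nuisance_{j}"
            )
    drift = cosine_drift_basis(frame_times, highpass_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append("constant" if k == 0 else f"drift_{k}")
    return DesignMatrix(
        matrix=np.column_stack(cols), columns=names,
        n_interest=n_interest, frame_times=frame_times,
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad}"
        )


def _ar1_prewhiten(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cochrane-Orcutt style AR(1) quasi-differencing with a pooled rho."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    num = np.sum(resid[1:] * resid[:-1])
    den = np.sum(resid[:-1] ** 2)
    rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
    Xw = X[1:] - rho * X[:-1]
    Yw = Y[1:] - rho * Y[:-1]
    return Xw, Yw


def estimate_glm(
    design: DesignMatrix,
    timeseries: np.ndarray,
    ar1: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit of one run; returns (betas, t-values, residual df).

    ``timeseries`` is (n_scans, n_voxels).  t = beta / (sigma *
    sqrt([(X'X)^-1]_jj)) per voxel with sigma^2 the residual variance on
    n - rank(X) degrees of freedom.  Voxels with zero residual variance get
    signed-infinite t with a warning.
    """
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need n_scans > n_columns, got {X.shape[0]} <= {X.shape[1]}"
        )
    _check_rank(X, design.columns)
    if ar1:
        X, Y = _ar1_prewhiten(X, Y)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df
    var_factor = np.sqrt(np.diag(xtx_inv))
    denom = np.sqrt(sigma2)[None, :] * var_factor[:, None]
    if np.any(sigma2 == 0):
        warnings.warn("zero residual variance in some voxels; t reported as "
                      "signed infinity", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, beta / np.where(denom == 0, 1.0, denom),
                     np.sign(beta) * np.inf)
        t = np.where((denom == 0) & (beta == 0), 0.0, t)
    return beta, t, float(df)


def fit_first_level(
    events: pd.DataFrame,
    run_timeseries: dict[int, np.ndarray],
    tr: float,
    nuisance: dict[int, np.ndarray] | None = None,
    ar1: bool = False,
) -> TMapSet:
    """Fit the three GLMs to every run and collect interest t-maps."""
    data: dict[tuple[int, str, str, int], np.ndarray] = {}
    dof: dict[int, float] = {}
    n_voxels = next(iter(run_timeseries.values())).shape[1]
    for run, Y in sorted(run_timeseries.items()):
        run_events = events[events["run"] == run]
        for scheme in SCHEMES:
            labeled = relabel_events(run_events, scheme)
            design = build_design(
                labeled, tr=tr, n_scans=Y.shape[0],
                nuisance=None if nuisance is None else nuisance.get(run),
            )
            _, t, df = estimate_glm(design, Y, ar1=ar1)
            dof[run] = df
            for j, name in enumerate(design.columns[: design.n_interest]):
                condition, label = name.split("/")
                data[(run, scheme, condition, int(label))] = t[j]
    return TMapSet(data=data, n_voxels=n_voxels, normalized=False, dof=dof)


def normalize_tmaps(tmaps: TMapSet) -> TMapSet:
    """Subtract, per voxel, the mean t over a run's 24 regressors.

    The mean is taken within one scheme's 24 columns (8 labels x 3
    conditions) for each run separately; applying it twice is a no-op.
    """
    runs = tmaps.runs()
    expected_per_run = len(CONDITIONS) * N_POSITIONS
    data: dict[tuple[int, str, str, int], np.ndarray] = {}
    for scheme in sorted({k[1] for k in tmaps.data}):
        for run in runs:
            keys = [k for k in tmaps.data if k[0] == run and k[1] == scheme]
            if len(keys) != expected_per_run:
                raise ValueError(
                    f"run {run}, scheme {scheme}: expected {expected_per_run} "
                    f"regressors, found {len(keys)}"
                )
            stack = np.stack([tmaps.data[k] for k in keys])
            mean = stack.mean(axis=0)
            for k in keys:
                data[k] = tmaps.data[k] - mean
    return TMapSet(data=data, n_voxels=tmaps.n_voxels, normalized=True,
                   dof=dict(tmaps.dof))
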