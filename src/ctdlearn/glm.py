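"""Event-level GLM estimation and multivariate noise normalization.

Event amplitudes are estimated per run with a beta-series GLM: each event
(room onset of a block, task-cue onset of a trial) gets one stick regressor
convolved with the canonical double-gamma HRF sampled at the TR.  Estimated
betas are then whitened across voxels by the symmetric inverse square root
of the (shrinkage-regularized) residual covariance, the standard
"univariate-noise-normalized" patterns used in pattern-similarity work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf

CONTEXT_ONSET = "context_onset"
TRIAL_CUE = "trial_cue"


@dataclass
class PatternSet:
    """Event x voxel activity patterns for one ROI with event metadata.

    ``events`` rows align 1:1 with ``data`` rows.  Columns: event_id, run,
    block, context, ctd, event_class (context_onset | trial_cue), trial,
    task, congruent, onset.
    """

    roi: str
    data: np.ndarray
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.events):
            raise ValueError("pattern rows must align with event metadata")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, mask) -> "PatternSet":
        mask = np.asarray(mask, dtype=bool)
        return PatternSet(self.roi, self.data[mask],
                          self.events.loc[mask].reset_index(drop=True))


def event_table(design) -> pd.DataFrame:
    """Build the session's event table: one room-onset event per block and
    one cue-onset event per trial, ordered by run, block, onset."""
    blocks = design.blocks
    trials = design.trials
    ctx_ev = pd.DataFrame(dict(
        run=blocks["run"], block=blocks["block"], context=blocks["context"],
        ctd=blocks["ctd"], event_class=CONTEXT_ONSET, trial=-1,
        task=-1, congruent=False, onset=blocks["room_onset"]))
    tr_ev = pd.DataFrame(dict(
        run=trials["run"], block=trials["block"], context=trials["context"],
        ctd=trials["ctd"], event_class=TRIAL_CUE, trial=trials["trial"],
        task=trials["task"], congruent=trials["congruent"],
        onset=trials["cue_onset"]))
    ev = pd.concat([ctx_ev, tr_ev], ignore_index=True)
    ev = ev.sort_values(["run", "block", "onset"], kind="stable")
    ev = ev.reset_index(drop=True)
    ev.insert(0, "event_id", np.arange(len(ev)))
    return ev


@dataclass
class EventDesignMatrix:
    """TR x regressor design: one HRF-convolved stick per event, then
    nuisance columns (constant, optional linear drift)."""

    matrix: np.ndarray
    event_ids: list
    nuisance_names: list

    @property
    def n_events(self) -> int:
        return len(self.event_ids)


_HRF_OVERSAMPLING = 40  # fine grid of tr / 40 for off-grid onsets


def canonical_hrf(tr: float = 2.0, oversampling: int = 1) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr / oversampling``
    seconds, normalized to unit peak."""
    h = spm_hrf(tr, oversampling=oversampling)
    return h / h.max()


def build_design_matrix(onsets, n_tr: int, tr: float = 2.0,
                        event_ids=None, add_drift: bool = True,
                        extra_nuisance=None) -> EventDesignMatrix:
    """One stick regressor per event onset, convolved with the canonical
    double-gamma HRF and sampled at the TR grid.

    Column k of event j is hrf(k*tr - onset_j); off-grid onsets are handled
    by evaluating the HRF on a fine grid (tr/40).
    """
    onsets = np.asarray(onsets, dtype=float)
    frame_times = np.arange(n_tr) * tr
    if onsets.size and onsets.max() >= n_tr * tr:
        raise ValueError(
            f"event onset {onsets.max():.2f}s beyond series end "
            f"({n_tr * tr:.2f}s)")
    h = canonical_hrf(tr, _HRF_OVERSAMPLING)
    dt = tr / _HRF_OVERSAMPLING
    cols = []
    for onset in onsets:
        lag = frame_times - onset
        idx = np.round(lag / dt).astype(int)
        valid = (idx >= 0) & (idx < h.size)
        col = np.zeros(n_tr)
        col[valid] = h[idx[valid]]
        cols.append(col)
    nuisance, names = [np.ones(n_tr)], ["constant"]
    if add_drift:
        nuisance.append(np.linspace(-1, 1, n_tr))
        names.append("drift")
    if extra_nuisance is not None:
        extra = np.atleast_2d(np.asarray(extra_nuisance, dtype=float))
        for k in range(extra.shape[0]):
            nuisance.append(extra[k])
            names.append(f"nuisance_{k}")
    X = np.column_stack(cols + nuisance) if cols else np.column_stack(nuisance)
    if event_ids is None:
        event_ids = list(range(onsets.size))
    return EventDesignMatrix(matrix=X, event_ids=list(event_ids),
                             nuisance_names=names)


def fit_event_glm(timeseries: np.ndarray, design: EventDesignMatrix):
    """Per-voxel least squares.  Returns (event betas, residuals).

    ``timeseries``: (n_tr, n_voxels); betas: (n_events, n_voxels) — nuisance
    coefficients are estimated but not returned; residuals: (n_tr, n_voxels).
    """
    Y = np.asarray(timeseries, dtype=float)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("timeseries and design have different TR counts")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (nearly) collinear columns via QR pivoting
        _, R = np.linalg.qr(X)
        bad = np.where(np.abs(np.diag(R)) < 1e-10 * np.abs(R[0, 0]))[0]
        labels = [design.event_ids[i] if i < design.n_events
                  else design.nuisance_names[i - design.n_events]
                  for i in bad]
        raise ValueError(f"rank-deficient design; collinear columns: {labels}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta[: design.n_events], resid


def noise_normalize(betas: np.ndarray, residuals: np.ndarray,
                    shrinkage: float = 0.1) -> np.ndarray:
    """Whiten event patterns: betas @ Sigma^(-1/2), with Sigma the voxel
    residual covariance shrunk toward its diagonal by ``shrinkage``."""
    betas = np.asarray(betas, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual rows to estimate covariance")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    sigma = np.cov(residuals, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    sigma = (1 - shrinkage) * sigma + shrinkage * np.diag(np.diag(sigma))
    w, V = np.linalg.eigh(sigma)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        raise ValueError(
            "residual covariance is singular; increase shrinkage")
    inv_sqrt = (V * (1.0 / np.sqrt(w))) @ V.T
    return betas @ inv_sqrt


def roi_univariate(data: np.ndarray) -> np.ndarray:
    """ROI-mean amplitude per event (mean across voxels)."""
    return np.asarray(data, dtype=float).mean(axis=1)


def exclude_events(events: pd.DataFrame, excluded_trials=None,
                   outlier_trs=None, outlier_window: float = 12.0,
                   drop_runs=()) -> np.ndarray:
    """Boolean retention mask over the event table.

    Drops (a) trial-cue events of behaviorally excluded trials, given as a
    set of (run, block, trial) keys; (b) events whose onset falls within
    ``outlier_window`` seconds before a flagged TR time (per-run dict
    run -> times, the hook for motion/intensity outliers); (c) all events in
    ``drop_runs`` (run-1 exclusion for the similarity analyses).
    """
    keep = np.ones(len(events), dtype=bool)
    if excluded_trials:
        keys = list(zip(events["run"], events["block"], events["trial"]))
        is_trial = (events["event_class"] == TRIAL_CUE).to_numpy()
        bad = np.array([k in excluded_trials for k in keys])
        keep &= ~(is_trial & bad)
    if outlier_trs:
        onset = events["onset"].to_numpy()
        run = events["run"].to_numpy()
        for r, times in outlier_trs.items():
            for t_out in np.atleast_1d(times):
                window = (run == r) & (onset > t_out - outlier_window) \
                    & (onset <= t_out)
                keep &= ~window
    if drop_runs:
        keep &= ~events["run"].isin(list(drop_runs)).to_numpy()
    return keep
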