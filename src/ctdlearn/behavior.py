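"""Trial filtering and model-based behavioral regressions.

The RT analyses exclude error trials, trials immediately following an error
(post-error slowing reflects a control process outside the learning models),
and slow outliers — RTs more than ``sd_mult`` standard deviations above the
median, with median and SD taken over the correct, non-post-error trials of
that subject.  Prediction errors are z-scored within subject before entering
the regressions; log-RT is modeled by OLS and accuracy by logistic
regression, each with {temporal PE, contextual PE, task, constant}.
Per-subject coefficients are then submitted to one-sample t-tests with
BH-FDR over the declared family of behavioral effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import GroupStats, RegressionResult, logistic_fit, ols_fit

RT_PREDICTORS = ("pe_temporal", "pe_contextual", "task", "constant")


@dataclass
class FilterReport:
    """Per-trial inclusion flags with mutually recorded reason codes."""

    included: np.ndarray  # bool, aligned with the trial table
    reasons: pd.DataFrame  # boolean columns: error, post_error, rt_outlier
    counts: dict

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def filter_trials(trials: pd.DataFrame, sd_mult: float = 2.5,
                  fmri_excluded=None) -> FilterReport:
    """Apply the RT-analysis exclusion rules.

    ``fmri_excluded``: optional boolean array flagging trials excluded on
    fMRI grounds (outlier-TR proximity); recorded as its own reason.
    """
    err = (trials["accuracy"].to_numpy() == 0)
    post = trials["post_error"].to_numpy().astype(bool)
    rt = trials["rt_ms"].to_numpy(dtype=float)

    clean = ~err & ~post
    if not clean.any():
        raise ValueError("all trials are error or post-error trials")
    med = np.median(rt[clean])
    sd = rt[clean].std(ddof=1)
    if np.isfinite(sd_mult):
        outlier = clean & (rt > med + sd_mult * sd)
    else:
        outlier = np.zeros_like(clean)

    fmri = (np.asarray(fmri_excluded, dtype=bool) if fmri_excluded is not None
            else np.zeros_like(err))
    reasons = pd.DataFrame(dict(error=err, post_error=post,
                                rt_outlier=outlier, fmri_excluded=fmri))
    included = ~(err | post | outlier | fmri)
    if not included.any():
        raise ValueError("all trials excluded by the filters")
    counts = {c: int(reasons[c].sum()) for c in reasons.columns}
    counts["included"] = int(included.sum())
    return FilterReport(included=included, reasons=reasons, counts=counts)


def normalize_predictors(values) -> np.ndarray:
    """Z-score with the n-1 (sample SD) convention."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot normalize a constant predictor")
    return (x - x.mean()) / sd


def _design(pe_temporal, pe_contextual, task):
    X = np.column_stack([
        normalize_predictors(pe_temporal),
        normalize_predictors(pe_contextual),
        np.asarray(task, dtype=float),
        np.ones(len(task)),
    ])
    return X


def fit_rt_model(log_rt, pe_temporal, pe_contextual, task) -> RegressionResult:
    """OLS of natural-log RT on z-scored PEs, task and a constant (over the
    included trials only; the caller applies ``filter_trials`` first)."""
    return ols_fit(np.asarray(log_rt, dtype=float),
                   _design(pe_temporal, pe_contextual, task),
                   RT_PREDICTORS, model="ols_logrt")


def fit_accuracy_model(accuracy, pe_temporal, pe_contextual,
                       task) -> RegressionResult:
    """Logistic regression of trial accuracy on z-scored PEs, task and a
    constant.  Non-convergence/separation is flagged, not raised."""
    y = np.asarray(accuracy)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("accuracy must be binary 0/1")
    return logistic_fit(y, _design(pe_temporal, pe_contextual, task),
                        RT_PREDICTORS, model="logistic_accuracy")


def quintile_summary(outcome, pe, n_bins: int = 5):
    """Rank trials by PE and split into ``n_bins`` equal-count bins
    (remainder spread over the lowest bins); returns per-bin means."""
    outcome = np.asarray(outcome, dtype=float)
    pe = np.asarray(pe, dtype=float)
    n = pe.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} trials, got {n}")
    order = np.argsort(pe, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    means = np.array([outcome[order[edges[i]:edges[i + 1]]].mean()
                      for i in range(n_bins)])
    return means


def group_quintiles(per_subject_means: np.ndarray):
    """Group mean +- SEM per bin over a (subjects x bins) array."""
    m = np.asarray(per_subject_means, dtype=float)
    return m.mean(axis=0), m.std(axis=0, ddof=1) / np.sqrt(m.shape[0])


def group_inference(coefs: pd.DataFrame, fdr_family=None) -> GroupStats:
    """One-sample t per coefficient over subjects; BH-FDR within the family
    of reported behavioral effects (default: all columns)."""
    return GroupStats.from_subject_coefficients(coefs, fdr_family=fdr_family)


def analyze_subject(trials: pd.DataFrame, pe_temporal, pe_contextual,
                    sd_mult: float = 2.5):
    """Convenience: filter, then fit both behavioral models for one subject.

    Returns (FilterReport, rt RegressionResult, accuracy RegressionResult).
    The accuracy model uses all trials (accuracy is the outcome); the RT
    model uses the filtered set.
    """
    rep = filter_trials(trials, sd_mult=sd_mult)
    inc = rep.included
    task = trials["task"].to_numpy()
    rt_res = fit_rt_model(np.log(trials["rt_ms"].to_numpy()[inc]),
                          np.asarray(pe_temporal)[inc],
                          np.asarray(pe_contextual)[inc], task[inc])
    acc_res = fit_accuracy_model(trials["accuracy"].to_numpy(),
                                 pe_temporal, pe_contextual, task)
    return rep, rt_res, acc_res
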