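"""Regressions linking reinstatement, hippocampal measures and behavior.

Four analyses, each fit per subject by OLS and summarized at the group
level with one-sample t-tests:

* trial-level reinstatement -> log-RT, with temporal PE, task and ROI-mean
  univariate activity as covariates of no interest (optionally also the
  contextual PE);
* block-level coupling — hippocampal context-context similarity in the
  three relation conditions plus hippocampal univariate activity as four
  predictors of block-wise cortical reinstatement, with the cortical ROI's
  univariate activity as a covariate;
* hippocampal measures -> log-RT, block-level predictors broadcast to the
  block's trials and signed by trial congruency (match +1 / mismatch -1);
* the across-subject correlation between hippocampal Same-CTD similarity
  and the behavioral effect of contextual prediction error.

Block-level predictors are z-scored within subject so group-level
coefficients are comparable across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .similarity import DIFFERENT_CTD, RELATIONS, SAME_CONTEXT, SAME_CTD
from .stats import RegressionResult, ols_fit


def _z(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor cannot be z-scored")
    return (x - x.mean()) / sd


def trial_rt_regression(df: pd.DataFrame,
                        include_contextual_pe: bool = False) -> RegressionResult:
    """Per-subject OLS of log-RT on trial-level reinstatement.

    ``df`` columns: log_rt, reinstatement, pe_temporal, task, roi_univariate
    (and pe_contextual when requested); rows are the subject's retained
    trials with a non-missing reinstatement value.
    """
    d = df.dropna(subset=["reinstatement"])
    names = ["reinstatement", "pe_temporal"]
    cols = [_z(d["reinstatement"]), _z(d["pe_temporal"])]
    if include_contextual_pe:
        names.append("pe_contextual")
        cols.append(_z(d["pe_contextual"]))
    names += ["task", "roi_univariate", "constant"]
    cols += [d["task"].to_numpy(dtype=float), _z(d["roi_univariate"]),
             np.ones(len(d))]
    return ols_fit(d["log_rt"].to_numpy(), np.column_stack(cols), names,
                   model="ols_logrt")


def block_level_similarity(cc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-block context-context similarity by condition.

    Each block's room-onset event is compared against all its eligible
    cross-run partners; every pair contributes to both blocks' values.
    Returns a frame indexed by (run, block) with one column per relation.
    """
    if cc_table.empty:
        raise ValueError("empty context-context similarity table")
    a = cc_table[["run_a", "block_a", "relation", "fisher_z"]].rename(
        columns={"run_a": "run", "block_a": "block"})
    b = cc_table[["run_b", "block_b", "relation", "fisher_z"]].rename(
        columns={"run_b": "run", "block_b": "block"})
    long = pd.concat([a, b], ignore_index=True)
    wide = long.groupby(["run", "block", "relation"])["fisher_z"].mean() \
        .unstack("relation")
    return wide.reindex(columns=list(RELATIONS))


def block_coupling_regression(outcome: pd.Series, hippo_blocks: pd.DataFrame,
                              hippo_univariate: pd.Series,
                              roi_univariate: pd.Series) -> RegressionResult:
    """Per-subject OLS of block-wise cortical reinstatement on the four
    hippocampal predictors plus the cortical univariate covariate.

    All inputs are indexed by (run, block); blocks missing any value are
    dropped.  Predictors are z-scored within subject.
    """
    df = pd.DataFrame(dict(outcome=outcome,
                           hippo_univariate=hippo_univariate,
                           roi_univariate=roi_univariate)) \
        .join(hippo_blocks, how="inner").dropna()
    names = [SAME_CONTEXT, SAME_CTD, DIFFERENT_CTD, "hippo_univariate",
             "roi_univariate", "constant"]
    X = np.column_stack([_z(df[SAME_CONTEXT]), _z(df[SAME_CTD]),
                         _z(df[DIFFERENT_CTD]), _z(df["hippo_univariate"]),
                         _z(df["roi_univariate"]), np.ones(len(df))])
    return ols_fit(df["outcome"].to_numpy(), X, names, model="ols_coupling")


def hippo_rt_regression(trials: pd.DataFrame, hippo_blocks: pd.DataFrame,
                        hippo_univariate: pd.Series) -> RegressionResult:
    """Per-subject OLS of trial log-RT on congruency-signed hippocampal
    block measures.

    ``trials`` columns: run, block, log_rt, congruent, pe_temporal, task —
    the retained trials.  Block-level predictors (three similarity
    conditions + univariate activity, z-scored within subject) are broadcast
    to the block's trials and multiplied by +1 on congruent and -1 on
    incongruent trials.
    """
    if trials["congruent"].nunique() < 2:
        raise ValueError("congruency factor is constant; signed predictors "
                         "are confounded with their unsigned versions")
    hb = hippo_blocks.copy()
    hb["hippo_univariate"] = hippo_univariate
    for c in hb.columns:
        hb[c] = _z(hb[c].to_numpy())
    d = trials.merge(hb.reset_index(), on=["run", "block"], how="inner") \
        .dropna(subset=list(hb.columns))
    sign = np.where(d["congruent"], 1.0, -1.0)
    names = [SAME_CONTEXT, SAME_CTD, DIFFERENT_CTD, "hippo_univariate",
             "pe_temporal", "task", "constant"]
    X = np.column_stack([sign * d[SAME_CONTEXT], sign * d[SAME_CTD],
                         sign * d[DIFFERENT_CTD],
                         sign * d["hippo_univariate"],
                         _z(d["pe_temporal"]), d["task"].to_numpy(dtype=float),
                         np.ones(len(d))])
    return ols_fit(d["log_rt"].to_numpy(), X, names, model="ols_hippo_rt")


def cross_subject_correlation(similarity_means, behavior_coefs):
    """Across-subject Pearson correlation between mean hippocampal Same-CTD
    similarity and the behavioral contextual-PE coefficient."""
    x = np.asarray(similarity_means, dtype=float)
    y = np.asarray(behavior_coefs, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must align across subjects")
    if x.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
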