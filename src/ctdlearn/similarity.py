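"""Cross-run pattern-similarity analyses of task-demand reinstatement.

Two families of comparisons, both Fisher-z Pearson correlations computed
strictly across scan runs:

* context-trial similarity — room-onset pattern of one block vs. task-cue
  pattern of an out-of-run trial.  Pairs fall in a 3 (context relation:
  same context / same CTD / different CTD) x 2 (congruency: the trial's
  required task matches / mismatches its own context's dominant demand)
  factorial.  The reinstatement test is the interaction contrast with
  weights (+1, -1, +1, -1, -2, +2) over (sc_con, sc_inc, sctd_con, sctd_inc,
  dctd_con, dctd_inc) — zero-sum and orthogonal to both main effects, the
  Different-CTD weight doubled to offset the 2:1 cell frequency.
* context-context similarity — room-onset patterns of two blocks, labeled
  by context relation only, used for the hippocampal representation and
  differentiation tests.

Because learning must precede retrieval, run 1 is excluded from the
reinstatement analyses; the context-representation validation test keeps
all runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import CONTEXT_ONSET, TRIAL_CUE, PatternSet
from .stats import paired_t

SAME_CONTEXT = "same_context"
SAME_CTD = "same_ctd"
DIFFERENT_CTD = "different_ctd"
RELATIONS = (SAME_CONTEXT, SAME_CTD, DIFFERENT_CTD)

CELL_ORDER = [(SAME_CONTEXT, True), (SAME_CONTEXT, False),
              (SAME_CTD, True), (SAME_CTD, False),
              (DIFFERENT_CTD, True), (DIFFERENT_CTD, False)]

R_CLAMP = 1.0 - 1e-7


def fisher_pearson(x, y) -> float:
    """Fisher-transformed Pearson correlation, r clamped to +-(1 - 1e-7)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("vectors must share length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input to fisher_pearson")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))


def _fisher_corr_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Fisher-z correlations between rows of A and rows of B."""
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    if (sa == 0).any() or (sb == 0).any():
        raise ValueError("zero-variance pattern encountered")
    Az = (A - A.mean(axis=1, keepdims=True)) / sa[:, None]
    Bz = (B - B.mean(axis=1, keepdims=True)) / sb[:, None]
    r = Az @ Bz.T / A.shape[1]
    return np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))


def label_pair(context_a: int, ctd_a: int, context_b: int, ctd_b: int,
               task_b: int | None = None):
    """Label a (context event A, event B) pair.

    Returns (relation, congruency) where congruency (None for
    context-context pairs) is defined by event B's required task against its
    own context's dominant demand.
    """
    if context_a == context_b:
        relation = SAME_CONTEXT
    elif ctd_a == ctd_b:
        relation = SAME_CTD
    else:
        relation = DIFFERENT_CTD
    congruent = None if task_b is None else bool(task_b == ctd_b)
    return relation, congruent


@dataclass(frozen=True)
class ContrastSpec:
    """Weights over the six (relation x congruency) cells in CELL_ORDER.

    Validated at construction: zero-sum and orthogonal to the congruency
    main effect and to the same-vs-different context-relation contrast.
    """

    weights: tuple = (1.0, -1.0, 1.0, -1.0, -2.0, 2.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != 6:
            raise ValueError("six cell weights required")
        if abs(w.sum()) > 1e-12:
            raise ValueError("contrast weights must sum to zero")
        congruency = np.array([1, -1, 1, -1, 1, -1], dtype=float)
        relation = np.array([1, 1, 1, 1, -2, -2], dtype=float)
        if abs(w @ congruency) > 1e-12 or abs(w @ relation) > 1e-12:
            raise ValueError("contrast must be orthogonal to both main effects")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _pairs_table(ctx_events: pd.DataFrame, other: pd.DataFrame,
                 z: np.ndarray, with_congruency: bool) -> pd.DataFrame:
    ia, ib = np.meshgrid(np.arange(len(ctx_events)), np.arange(len(other)),
                         indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    run_a = ctx_events["run"].to_numpy()[ia]
    run_b = other["run"].to_numpy()[ib]
    cross = run_a != run_b
    ia, ib = ia[cross], ib[cross]
    ctx_a = ctx_events["context"].to_numpy()[ia]
    ctd_a = ctx_events["ctd"].to_numpy()[ia]
    ctx_b = other["context"].to_numpy()[ib]
    ctd_b = other["ctd"].to_numpy()[ib]
    relation = np.where(ctx_a == ctx_b, SAME_CONTEXT,
                        np.where(ctd_a == ctd_b, SAME_CTD, DIFFERENT_CTD))
    tab = pd.DataFrame(dict(
        event_a=ctx_events["event_id"].to_numpy()[ia],
        event_b=other["event_id"].to_numpy()[ib],
        run_a=ctx_events["run"].to_numpy()[ia],
        run_b=other["run"].to_numpy()[ib],
        block_a=ctx_events["block"].to_numpy()[ia],
        block_b=other["block"].to_numpy()[ib],
        relation=relation,
        fisher_z=z[ia, ib],
    ))
    if with_congruency:
        tab["congruent"] = (other["task"].to_numpy()[ib]
                            == ctd_b).astype(bool)
    return tab


def context_trial_similarity(pset: PatternSet, runs=None,
                             include_trials=None) -> pd.DataFrame:
    """All cross-run (room onset, trial cue) similarity pairs.

    ``runs``: runs to include (default: all but run 0, the first run);
    ``include_trials``: optional boolean mask over ``pset.events`` retaining
    trial events (behavioral/fMRI exclusions); room-onset events are always
    retained within ``runs``.
    """
    ev = pset.events
    if runs is None:
        runs = sorted(ev["run"].unique())[1:]
    in_runs = ev["run"].isin(list(runs)).to_numpy()
    is_ctx = (ev["event_class"] == CONTEXT_ONSET).to_numpy()
    is_trial = (ev["event_class"] == TRIAL_CUE).to_numpy()
    keep_trial = is_trial & in_runs
    if include_trials is not None:
        keep_trial &= np.asarray(include_trials, dtype=bool)
    keep_ctx = is_ctx & in_runs
    if not keep_ctx.any() or not keep_trial.any():
        raise ValueError("no usable events for context-trial similarity")
    ctx_ev = ev.loc[keep_ctx].reset_index(drop=True)
    tr_ev = ev.loc[keep_trial].reset_index(drop=True)
    z = _fisher_corr_block(pset.data[keep_ctx], pset.data[keep_trial])
    return _pairs_table(ctx_ev, tr_ev, z, with_congruency=True)


def context_context_similarity(pset: PatternSet, runs=None) -> pd.DataFrame:
    """All cross-run pairs of room-onset events (unordered, no duplicates),
    labeled by context relation only.  Default: all runs."""
    ev = pset.events
    is_ctx = (ev["event_class"] == CONTEXT_ONSET).to_numpy()
    if runs is not None:
        is_ctx &= ev["run"].isin(list(runs)).to_numpy()
    if not is_ctx.any():
        raise ValueError("no room-onset events in the requested runs")
    ctx_ev = ev.loc[is_ctx].reset_index(drop=True)
    z = _fisher_corr_block(pset.data[is_ctx], pset.data[is_ctx])
    tab = _pairs_table(ctx_ev, ctx_ev, z, with_congruency=False)
    # keep each unordered pair once
    tab = tab[tab["event_a"] < tab["event_b"]].reset_index(drop=True)
    return tab


def cell_means(table: pd.DataFrame) -> pd.Series:
    """Unweighted mean Fisher-z per (relation x congruency) cell, ordered as
    CELL_ORDER; empty cells come back as NaN (flagged missing)."""
    grouped = table.groupby(["relation", "congruent"])["fisher_z"].mean()
    vals = [grouped.get((rel, con), np.nan) for rel, con in CELL_ORDER]
    idx = pd.MultiIndex.from_tuples(CELL_ORDER, names=["relation", "congruent"])
    return pd.Series(vals, index=idx, name="fisher_z")


def reinstatement_contrast(cells: pd.Series,
                           spec: ContrastSpec = ContrastSpec()) -> float:
    """Interaction contrast over the six cell means."""
    vals = cells.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing cells; cannot evaluate the contrast")
    return float(vals @ spec.as_array())


def congruency_effect(cells: pd.Series, subset: str = "same_pooled") -> float:
    """(congruent - incongruent) within a relation subset.

    ``same_pooled`` averages the Same Context and Same CTD cells before
    differencing; ``same_ctd`` / ``different_ctd`` use that relation alone.
    """
    c = cells
    if subset == "same_pooled":
        con = (c[(SAME_CONTEXT, True)] + c[(SAME_CTD, True)]) / 2
        inc = (c[(SAME_CONTEXT, False)] + c[(SAME_CTD, False)]) / 2
    elif subset in (SAME_CTD, DIFFERENT_CTD):
        con, inc = c[(subset, True)], c[(subset, False)]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return float(con - inc)


def trial_reinstatement(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial signed reinstatement (match/mismatch contrast).

    For each trial event: mean Fisher-z over its Same Context and Same CTD
    pairs, multiplied by +1 if the trial is congruent and -1 otherwise.
    The Different CTD relation is excluded.  Returns a frame indexed by
    trial event id with columns run, block, value.
    """
    sub = table[table["relation"].isin([SAME_CONTEXT, SAME_CTD])]
    if sub.empty:
        return pd.DataFrame(columns=["run", "block", "value"])
    agg = sub.groupby("event_b").agg(
        mean_z=("fisher_z", "mean"), congruent=("congruent", "first"),
        run=("run_b", "first"), block=("block_b", "first"))
    sign = np.where(agg["congruent"], 1.0, -1.0)
    return pd.DataFrame(dict(run=agg["run"], block=agg["block"],
                             value=sign * agg["mean_z"]))


def block_reinstatement(table: pd.DataFrame) -> pd.Series:
    """Block-level reinstatement, indexed by (run, block).

    Reinstatement is expressed at the room onset of a block, so the block's
    value is the match/mismatch contrast over the pairs between *that
    block's room-onset event* and its out-of-run trials: mean Fisher-z over
    congruent pairs minus mean over incongruent pairs, within the Same
    Context and Same CTD relations.  Blocks lacking either congruency cell
    are returned as NaN.
    """
    sub = table[table["relation"].isin([SAME_CONTEXT, SAME_CTD])]
    if sub.empty:
        return pd.Series(dtype=float)
    m = sub.groupby(["run_a", "block_a", "congruent"])["fisher_z"].mean() \
        .unstack("congruent")
    m = m.reindex(columns=[True, False])
    out = m[True] - m[False]
    out.index.names = ["run", "block"]
    return out


def condition_means(cc_table: pd.DataFrame) -> pd.Series:
    """Mean Fisher-z per context relation of a context-context table."""
    m = cc_table.groupby("relation")["fisher_z"].mean()
    return m.reindex(RELATIONS)


def differentiation_tests(cc_tables_by_subject: dict,
                          validation_runs=None,
                          differentiation_runs=None,
                          run_profile: bool = True) -> dict:
    """Group-level context-representation and differentiation tests.

    ``cc_tables_by_subject``: {subject: context-context similarity table
    over all runs}.  The validation test (Same Context > Different CTD) uses
    all runs by default; the differentiation test (Same CTD < Different CTD)
    uses runs 2+ by default.  Also returns per-run condition means for the
    temporal-profile summary.
    """
    rows, run_rows = [], []
    for subj, tab in cc_tables_by_subject.items():
        def _means(runs):
            sub = tab
            if runs is not None:
                sub = tab[tab["run_a"].isin(runs) & tab["run_b"].isin(runs)]
            return condition_means(sub)

        val = _means(validation_runs)
        if differentiation_runs is None:
            runs_all = sorted(set(tab["run_a"]) | set(tab["run_b"]))
            diff_runs = runs_all[1:]
        else:
            diff_runs = differentiation_runs
        dif = _means(diff_runs)
        rows.append(dict(subject=subj,
                         val_same_context=val[SAME_CONTEXT],
                         val_different_ctd=val[DIFFERENT_CTD],
                         dif_same_ctd=dif[SAME_CTD],
                         dif_different_ctd=dif[DIFFERENT_CTD]))
        if run_profile:
            for r in sorted(set(tab["run_a"]) | set(tab["run_b"])):
                sub = tab[(tab["run_a"] == r) | (tab["run_b"] == r)]
                m = condition_means(sub)
                run_rows.append(dict(subject=subj, run=r, **m.to_dict()))
    df = pd.DataFrame(rows)
    return dict(
        validation=paired_t(df["val_same_context"], df["val_different_ctd"]),
        differentiation=paired_t(df["dif_same_ctd"], df["dif_different_ctd"]),
        per_subject=df,
        run_profile=pd.DataFrame(run_rows),
    )
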