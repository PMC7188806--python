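"""Delta-rule learners of task demand and their grid-search fitting.

Two learners model how a subject predicts the upcoming task (face = 0,
object = 1):

* the *temporal* model keeps a single running prediction P_o updated after
  every trial regardless of context;
* the *contextual* model keeps one independent prediction per spatial
  context and on each trial only the current context's learner predicts and
  updates, so it can acquire the context's dominant task demand.

Both use the same delta rule, ``P <- P + alpha * (T - P)``, from a neutral
initial prediction of 0.5.  The per-trial unsigned prediction error is
``|T(t) - P(t)|`` where P(t) is the prediction entering the trial — i.e. the
discrepancy between the predicted and the actually required task.  A
``lagged`` flag reproduces the alternative bookkeeping in which trial t
carries the previous step's error.

Learning rates are fit per subject by exhaustive grid search: for each
(alpha_temporal, alpha_contextual) lattice point both prediction-error
series are computed and log-RT is regressed on {temporal PE, contextual PE,
task, constant}; the pair minimizing the residual sum of squares wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LearnerParams:
    alpha: float
    p0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")


@dataclass(frozen=True)
class PredictionSeries:
    """Per-trial predictions and unsigned prediction errors of one learner."""

    prediction: np.ndarray
    pe: np.ndarray
    model: str  # "temporal" | "contextual"

    def __post_init__(self) -> None:
        for arr in (self.prediction, self.pe):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("predictions and PEs must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.prediction)


def delta_update(p: float, target: int, alpha: float) -> float:
    """One delta-rule step: p + alpha * (target - p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if target not in (0, 1):
        raise ValueError(f"target must be 0 or 1, got {target}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return p + alpha * (target - p)


def run_temporal_model(tasks, params: LearnerParams,
                       lagged: bool = False) -> PredictionSeries:
    """Run the single context-insensitive learner over a 0/1 task sequence.

    ``prediction[t]`` is the state *before* observing trial t's task;
    ``pe[t] = |tasks[t] - prediction[t]|`` (or the previous step's error when
    ``lagged``, with the first trial's lagged error defined against p0).
    """
    tasks = np.asarray(tasks, dtype=float)
    if tasks.size == 0:
        raise ValueError("tasks must be non-empty")
    pred = np.empty(tasks.size)
    p = params.p0
    a = params.alpha
    for t, task in enumerate(tasks):
        pred[t] = p
        p = p + a * (task - p)
    pe = np.abs(tasks - pred)
    if lagged:
        pe = np.concatenate([[abs(tasks[0] - params.p0)], pe[:-1]])
    return PredictionSeries(prediction=pred, pe=pe, model="temporal")


def run_contextual_model(tasks, contexts, params: LearnerParams,
                         lagged: bool = False) -> PredictionSeries:
    """Run one delta-rule learner per context over aligned task/context
    sequences; only the current context's learner predicts and updates."""
    tasks = np.asarray(tasks, dtype=float)
    contexts = np.asarray(contexts)
    if tasks.size == 0:
        raise ValueError("tasks must be non-empty")
    if contexts.shape != tasks.shape:
        raise ValueError("contexts must align with tasks")
    states: dict = {}
    pred = np.empty(tasks.size)
    a = params.alpha
    for t, (task, ctx) in enumerate(zip(tasks, contexts)):
        key = ctx.item() if hasattr(ctx, "item") else ctx
        p = states.get(key, params.p0)
        pred[t] = p
        states[key] = p + a * (task - p)
    pe = np.abs(tasks - pred)
    if lagged:
        # lagged PE within each context's own subsequence
        pe_lag = np.empty_like(pe)
        last: dict = {}
        for t, ctx in enumerate(contexts):
            key = ctx.item() if hasattr(ctx, "item") else ctx
            pe_lag[t] = last.get(key, abs(tasks[t] - params.p0))
            last[key] = pe[t]
        pe = pe_lag
    return PredictionSeries(prediction=pred, pe=pe, model="contextual")


def prediction_error(series: PredictionSeries, tasks) -> np.ndarray:
    """Unsigned per-trial prediction error |T(t) - P(t)|."""
    tasks = np.asarray(tasks, dtype=float)
    if tasks.shape != series.prediction.shape:
        raise ValueError("tasks must align with the prediction series")
    return np.abs(tasks - series.prediction)


def _pe_matrix(tasks: np.ndarray, alphas: np.ndarray, contexts=None,
               p0: float = 0.5) -> np.ndarray:
    """(n_alphas, n_trials) unsigned-PE matrix, vectorized over alpha."""
    n = tasks.size
    pes = np.empty((alphas.size, n))
    if contexts is None:
        p = np.full(alphas.size, p0)
        for t in range(n):
            pes[:, t] = np.abs(tasks[t] - p)
            p = p + alphas * (tasks[t] - p)
    else:
        uniq = {c: i for i, c in enumerate(pd.unique(contexts))}
        p = np.full((alphas.size, len(uniq)), p0)
        for t in range(n):
            j = uniq[contexts[t]]
            pes[:, t] = np.abs(tasks[t] - p[:, j])
            p[:, j] = p[:, j] + alphas * (tasks[t] - p[:, j])
    return pes


@dataclass(frozen=True)
class GridSearchResult:
    alpha_temporal: float
    alpha_contextual: float
    sse: float
    grid: np.ndarray  # evaluated lattice of alphas
    sse_grid: np.ndarray  # (n_alpha_t, n_alpha_c) residual sums of squares


def grid_search_alphas(tasks, contexts, log_rt, include,
                       grid=None, p0: float = 0.5) -> GridSearchResult:
    """Joint grid search for the temporal and contextual learning rates.

    For every lattice pair, both PE series are computed over the *full*
    trial sequence, then log-RT is regressed on {temporal PE, contextual PE,
    task, constant} over the included trials only; the pair with minimal SSE
    wins.  Ties break toward the smallest contextual alpha, then the
    smallest temporal alpha.

    Parameters
    ----------
    include : boolean mask of trials entering the regression (RT filters
        applied by the caller).
    grid : 1-D array of candidate rates, default 0.01..0.99 step 0.01.
    """
    tasks = np.asarray(tasks, dtype=float)
    contexts = np.asarray(contexts)
    log_rt = np.asarray(log_rt, dtype=float)
    include = np.asarray(include, dtype=bool)
    if grid is None:
        grid = np.round(np.arange(0.01, 0.995, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    y = log_rt[include]
    n = y.size
    if n < 4:
        raise ValueError(f"only {n} trials for a 4-predictor regression")
    y = y - y.mean()  # constant is in the model; centering tames round-off

    PT = _pe_matrix(tasks, grid, None, p0)[:, include]          # (g, n)
    PC = _pe_matrix(tasks, grid, contexts, p0)[:, include]      # (g, n)
    task = tasks[include]
    ones = np.ones(n)

    g = grid.size
    # Gram-matrix blocks for X = [pe_t_i, pe_c_j, task, 1], all (i, j) pairs
    tt = np.einsum("in,in->i", PT, PT)           # (g,)
    cc = np.einsum("jn,jn->j", PC, PC)           # (g,)
    tc = PT @ PC.T                               # (g, g)
    t_task = PT @ task
    c_task = PC @ task
    t_one = PT @ ones
    c_one = PC @ ones
    t_y = PT @ y
    c_y = PC @ y
    task_task = task @ task
    task_one = task.sum()
    task_y = task @ y
    one_y = y.sum()
    yy = y @ y

    G = np.empty((g, g, 4, 4))
    G[..., 0, 0] = tt[:, None]
    G[..., 1, 1] = cc[None, :]
    G[..., 0, 1] = G[..., 1, 0] = tc
    G[..., 0, 2] = G[..., 2, 0] = t_task[:, None]
    G[..., 1, 2] = G[..., 2, 1] = c_task[None, :]
    G[..., 0, 3] = G[..., 3, 0] = t_one[:, None]
    G[..., 1, 3] = G[..., 3, 1] = c_one[None, :]
    G[..., 2, 2] = task_task
    G[..., 2, 3] = G[..., 3, 2] = task_one
    G[..., 3, 3] = float(n)
    b = np.empty((g, g, 4))
    b[..., 0] = t_y[:, None]
    b[..., 1] = c_y[None, :]
    b[..., 2] = task_y
    b[..., 3] = one_y

    beta = np.linalg.solve(G, b[..., None])[..., 0]
    sse = yy - np.einsum("ijk,ijk->ij", b, beta)
    sse = np.maximum(sse, 0.0)

    # tie-break: smallest alpha_c, then smallest alpha_t, at minimal SSE
    best = np.min(sse)
    atol = 1e-9 * max(1.0, yy / n)
    it, ic = np.where(np.isclose(sse, best, rtol=0, atol=atol))
    order = np.lexsort((grid[it], grid[ic]))
    i, j = it[order[0]], ic[order[0]]
    return GridSearchResult(alpha_temporal=float(grid[i]),
                            alpha_contextual=float(grid[j]),
                            sse=float(sse[i, j]), grid=grid, sse_grid=sse)
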