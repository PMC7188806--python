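"""Synthetic behavior and multi-voxel patterns with planted effect structure.

The generator produces, for each simulated subject:

* behavior — log-RT built from the delta-rule learners' prediction errors
  (temporal and contextual, z-scored), the required task, an optional
  reinstatement term, and Gaussian noise; accuracy from a logistic model in
  the same predictors;
* block latents — per-block fluctuations of hippocampal context-code
  overlap (w), hippocampal amplitude (u), cortical amplitude (v), and the
  cortical reinstatement gain g = g0 + gamma_h*w + gamma_u*u + noise;
* multi-voxel patterns per ROI — four context codes constructed with an
  exact target correlation matrix (orthonormal mean-zero basis mixed by the
  matrix square root of the target Gram matrix), two orthogonal task codes,
  per-voxel Gaussian noise.  Trial patterns carry context + required-task
  codes; room-onset patterns carry the context code plus, in cortical ROIs,
  the block's dominant-task code scaled by the reinstatement gain.  The
  hippocampal ROI carries context codes, a same-CTD partner-code overlap
  fluctuation and amplitude fluctuations, but no task reinstatement.

Every effect a downstream analysis tests has a named parameter here, so
null and planted-effect datasets differ only in those parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignSpec, SessionDesign, generate_design
from .glm import (CONTEXT_ONSET, PatternSet, build_design_matrix,
                  event_table)
from .rl import LearnerParams, run_contextual_model, run_temporal_model

HIPPOCAMPUS = "hippocampus"


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class GenerativeParams:
    """Planted truth for the behavioral forward model.

    RT coefficients act on natural-log RT (ms); PE coefficients apply to
    z-scored prediction-error series computed at the true learning rates.
    ``*_sd`` fields are between-subject SDs of the corresponding
    coefficient (random effects around the group mean).
    """

    true_alpha_temporal: float = 0.30
    true_alpha_contextual: float = 0.10
    beta0: float = 7.0
    beta_temporal_pe: float = 0.03
    beta_contextual_pe: float = 0.01
    beta_task: float = 0.057
    beta_reinstatement: float = -0.01
    beta_temporal_pe_sd: float = 0.02
    beta_contextual_pe_sd: float = 0.02
    beta_reinstatement_sd: float = 0.005
    rt_noise_sd: float = 0.05
    acc_intercept: float = 2.3
    acc_beta_temporal: float = 0.09
    acc_beta_contextual: float = -0.19
    acc_beta_task: float = -0.10
    acc_beta_temporal_sd: float = 0.25
    acc_beta_contextual_sd: float = 0.15
    # change in the contextual accuracy coefficient per unit of the shared
    # subject latent that also raises hippocampal same-CTD similarity
    # (positive: weaker pattern separation goes with weaker CTD modulation)
    xs_acc_slope: float = 0.20

    def __post_init__(self) -> None:
        for name in ("true_alpha_temporal", "true_alpha_contextual"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.rt_noise_sd <= 0:
            raise ValueError("rt_noise_sd must be positive")


@dataclass(frozen=True)
class ROIParams:
    """Pattern-construction parameters for one ROI.

    ``rho_same_ctd``/``rho_diff_ctd`` are target correlations between the
    context codes of rooms sharing / not sharing a dominant task;
    ``rho_same_ctd`` may be a per-run tuple to let differentiation emerge
    over runs.  ``overlap_sd`` scales a per-block fluctuation of the
    same-CTD partner code mixed into room-onset patterns (hippocampus);
    ``amp_fluct_sd`` scales per-block uniform amplitude fluctuations that
    drive ROI-mean (univariate) activity; ``noise_sd`` is the per-voxel
    Gaussian noise SD.
    """

    n_voxels: int = 60
    rho_same_ctd: object = 0.2
    rho_diff_ctd: float = 0.0
    amp_context: float = 1.0
    amp_task: float = 1.0
    reinstatement: bool = True
    overlap_sd: float = 0.0
    amp_fluct_sd: float = 0.2
    noise_sd: float = 0.35

    def rho_same_for_run(self, run: int) -> float:
        if np.isscalar(self.rho_same_ctd):
            return float(self.rho_same_ctd)
        return float(self.rho_same_ctd[run])

    def __post_init__(self) -> None:
        rhos = ([self.rho_same_ctd] if np.isscalar(self.rho_same_ctd)
                else list(self.rho_same_ctd)) + [self.rho_diff_ctd]
        for r in rhos:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation target {r} outside [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_rois() -> dict:
    """Default ROI set: one frontoparietal ROI carrying CTD reinstatement
    and a hippocampal ROI with differentiated context codes (same-CTD
    similarity below different-CTD from run 2 on) and no reinstatement."""
    return {
        "dlpfc": ROIParams(),
        HIPPOCAMPUS: ROIParams(
            reinstatement=False,
            rho_same_ctd=(0.22, 0.08, 0.08, 0.08, 0.08, 0.08),
            rho_diff_ctd=0.22, overlap_sd=0.30, amp_fluct_sd=0.3),
    }


@dataclass(frozen=True)
class NeuralParams:
    """Planted truth for the neural forward model.

    The cortical reinstatement gain of block b is
    ``g_b = gain0 + gamma_h * w_b + gamma_u * u_b + N(0, gain_noise_sd)``
    with w_b the hippocampal same-CTD overlap fluctuation and u_b the
    hippocampal amplitude fluctuation (both standard normal latents).
    """

    rois: dict = field(default_factory=default_rois)
    gain0: float = 0.4
    gamma_h: float = 0.15
    gamma_u: float = 0.15
    gain_noise_sd: float = 0.15
    # SD of the subject-level offset to the hippocampal same-CTD correlation
    # target (shared latent with the behavioral CTD modulation)
    xs_hippo_sd: float = 0.08
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.gain_noise_sd < 0:
            raise ValueError("gain_noise_sd must be non-negative")

    def null(self) -> "NeuralParams":
        """A copy with no reinstatement and no hippocampal differentiation
        or coupling — the null generator for calibration."""
        rois = {name: replace(p, rho_same_ctd=p.rho_diff_ctd, overlap_sd=0.0)
                for name, p in self.rois.items()}
        return replace(self, rois=rois, gain0=0.0, gamma_h=0.0, gamma_u=0.0,
                       xs_hippo_sd=0.0)


def generate_latents(design: SessionDesign, nparams: NeuralParams,
                     seed) -> pd.DataFrame:
    """Per-block latent fluctuations and the implied reinstatement gain."""
    rng = np.random.default_rng(seed)
    blocks = design.blocks
    n = len(blocks)
    w = rng.standard_normal(n)
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    gain = (nparams.gain0 + nparams.gamma_h * w + nparams.gamma_u * u
            + nparams.gain_noise_sd * rng.standard_normal(n))
    out = blocks[["run", "block", "context", "ctd"]].copy()
    out["hippo_overlap"] = w
    out["hippo_amp"] = u
    out["cortical_amp"] = v
    out["gain"] = gain
    return out


def generate_behavior(design: SessionDesign, params: GenerativeParams,
                      seed, block_gain=None,
                      acc_contextual_shift: float = 0.0) -> pd.DataFrame:
    """Fill the trial table with rt (ms), accuracy and post_error flags.

    ``block_gain``: optional per-block reinstatement gain (aligned with
    ``design.blocks``); when given and ``beta_reinstatement`` is non-zero,
    log-RT includes ``beta_reinstatement * z(sign * gain)`` where sign is +1
    on congruent and -1 on incongruent trials — the same match/mismatch
    convention the analyses use to measure reinstatement.
    ``acc_contextual_shift``: subject-level offset to the contextual
    accuracy coefficient (the behavioral end of the cross-subject link).
    """
    rng = np.random.default_rng(seed)
    trials = design.trials.copy()
    tasks = trials["task"].to_numpy()
    contexts = trials["context"].to_numpy()

    pe_t = run_temporal_model(
        tasks, LearnerParams(params.true_alpha_temporal)).pe
    pe_c = run_contextual_model(
        tasks, contexts, LearnerParams(params.true_alpha_contextual)).pe
    z_t, z_c = _zscore(pe_t), _zscore(pe_c)

    b_t = params.beta_temporal_pe + params.beta_temporal_pe_sd * rng.standard_normal()
    b_c = params.beta_contextual_pe + params.beta_contextual_pe_sd * rng.standard_normal()
    a_t = params.acc_beta_temporal + params.acc_beta_temporal_sd * rng.standard_normal()
    a_c = (params.acc_beta_contextual + acc_contextual_shift
           + params.acc_beta_contextual_sd * rng.standard_normal())

    log_rt = (params.beta0 + b_t * z_t + b_c * z_c
              + params.beta_task * tasks)
    if block_gain is not None and params.beta_reinstatement != 0.0:
        gain = np.asarray(block_gain, dtype=float)
        # blocks are ordered run-major, block-minor in design.blocks
        flat = (trials["run"].to_numpy() * design.spec.n_blocks_per_run
                + trials["block"].to_numpy())
        g_trial = gain[flat]
        sign = np.where(trials["congruent"], 1.0, -1.0)
        b_r = (params.beta_reinstatement
               + params.beta_reinstatement_sd * rng.standard_normal())
        log_rt = log_rt + b_r * _zscore(sign * g_trial)
    log_rt = log_rt + params.rt_noise_sd * rng.standard_normal(len(trials))

    logit = (params.acc_intercept + a_t * z_t + a_c * z_c
             + params.acc_beta_task * tasks)
    p_correct = 1.0 / (1.0 + np.exp(-logit))
    accuracy = (rng.random(len(trials)) < p_correct).astype(int)

    post_error = np.zeros(len(trials), dtype=bool)
    prev_err = np.concatenate([[False], accuracy[:-1] == 0])
    same_block = np.concatenate(
        [[False], (trials["block"].to_numpy()[1:] == trials["block"].to_numpy()[:-1])
         & (trials["run"].to_numpy()[1:] == trials["run"].to_numpy()[:-1])])
    post_error = prev_err & same_block

    trials["rt_ms"] = np.exp(log_rt)
    trials["accuracy"] = accuracy
    trials["post_error"] = post_error
    return trials


def _mean_zero_orthonormal(n_voxels: int, n_cols: int, rng) -> np.ndarray:
    """Columns are orthonormal, each exactly mean-zero (orthogonal to 1)."""
    if n_voxels < n_cols + 1:
        raise ValueError(f"need at least {n_cols + 1} voxels")
    M = np.column_stack([np.ones(n_voxels),
                         rng.standard_normal((n_voxels, n_cols))])
    Q, _ = np.linalg.qr(M)
    return Q[:, 1:]


def _context_gram(ctd_assignment, rho_same: float, rho_diff: float) -> np.ndarray:
    ctd = np.asarray(ctd_assignment)
    same = ctd[:, None] == ctd[None, :]
    G = np.where(same, rho_same, rho_diff)
    np.fill_diagonal(G, 1.0)
    return G


def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-10:
        raise ValueError(
            f"context-code correlation target is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})")
    return (V * np.sqrt(np.clip(w, 0, None))) @ V.T


def _context_codes(basis: np.ndarray, spec: DesignSpec, roi: ROIParams,
                   n_runs: int, rho_same_shift: float = 0.0) -> np.ndarray:
    """(n_runs, n_contexts, n_voxels) context codes; for constant targets
    the codes are identical across runs."""
    codes = np.empty((n_runs, spec.n_contexts, basis.shape[0]))
    for r in range(n_runs):
        rho_same = np.clip(roi.rho_same_for_run(r) + rho_same_shift,
                           -0.95, 0.95)
        G = _context_gram(spec.ctd_assignment, rho_same, roi.rho_diff_ctd)
        codes[r] = (basis @ _psd_sqrt(G)).T
    return codes


def generate_patterns(design: SessionDesign, behavior: pd.DataFrame,
                      nparams: NeuralParams, seed,
                      latents: pd.DataFrame | None = None,
                      hippo_rho_shift: float = 0.0) -> dict:
    """Event-level patterns per ROI, planted per the module docstring.

    Returns {roi_name: PatternSet}.  ``behavior`` supplies trial metadata
    (generation itself does not depend on RT/accuracy); ``latents`` defaults
    to a fresh draw from ``generate_latents``.  ``hippo_rho_shift`` offsets
    the same-CTD correlation target of non-reinstatement (hippocampal) ROIs
    — the neural end of the cross-subject link.
    """
    rng = np.random.default_rng(seed)
    spec = design.spec
    events = event_table(design)
    if latents is None:
        latents = generate_latents(design, nparams, rng.integers(2**31))
    lat_ev = events[["run", "block"]].merge(
        latents, on=["run", "block"], how="left", sort=False)

    ctd = np.asarray(spec.ctd_assignment)
    # same-CTD partner of each context (other room with the same demand)
    partner = np.array([next(j for j in range(spec.n_contexts)
                             if j != i and ctd[j] == ctd[i])
                        for i in range(spec.n_contexts)])

    run = events["run"].to_numpy()
    context = events["context"].to_numpy()
    ev_ctd = events["ctd"].to_numpy()
    task = events["task"].to_numpy()
    is_ctx = (events["event_class"] == CONTEXT_ONSET).to_numpy()
    gain = lat_ev["gain"].to_numpy()
    w = lat_ev["hippo_overlap"].to_numpy()
    u = lat_ev["hippo_amp"].to_numpy()
    v = lat_ev["cortical_amp"].to_numpy()

    out = {}
    for name, roi in nparams.rois.items():
        basis = _mean_zero_orthonormal(roi.n_voxels, spec.n_contexts + 2, rng)
        ctx_basis, task_basis = basis[:, : spec.n_contexts], basis[:, spec.n_contexts:]
        shift = 0.0 if roi.reinstatement else hippo_rho_shift
        codes = _context_codes(ctx_basis, spec, roi, spec.n_runs, shift)
        task_codes = task_basis.T  # (2, n_voxels): face, object

        data = roi.amp_context * codes[run, context]
        if roi.reinstatement:
            data[is_ctx] += (gain[is_ctx, None] * roi.amp_task
                             * task_codes[ev_ctd[is_ctx]])
            data[is_ctx] += roi.amp_fluct_sd * v[is_ctx, None]
            data[~is_ctx] += roi.amp_task * task_codes[task[~is_ctx]]
        else:
            data[is_ctx] += (roi.overlap_sd * w[is_ctx, None]
                             * codes[run[is_ctx], partner[context[is_ctx]]])
            data[is_ctx] += roi.amp_fluct_sd * u[is_ctx, None]
        if roi.noise_sd > 0:
            data = data + roi.noise_sd * rng.standard_normal(data.shape)
        out[name] = PatternSet(roi=name, data=data, events=events.copy())
    return out


def generate_timeseries(design: SessionDesign, patterns: dict,
                        nparams: NeuralParams, seed,
                        noise_sd: float = 0.0, pad_s: float = 24.0) -> dict:
    """Forward-convolve event patterns into voxel x TR series per run.

    Each event contributes its pattern scaled by the canonical HRF sampled
    at the TR; additive white Gaussian noise with SD ``noise_sd``.  Returns
    {roi: {run: (n_tr, n_voxels) array}} plus per-run design info under the
    key ``"designs"`` ({run: EventDesignMatrix}).
    """
    rng = np.random.default_rng(seed)
    tr = nparams.tr
    events_any = next(iter(patterns.values())).events
    out: dict = {"designs": {}}
    for run in sorted(events_any["run"].unique()):
        mask = (events_any["run"] == run).to_numpy()
        ev = events_any.loc[mask]
        n_tr = int(np.ceil((ev["onset"].max() + pad_s) / tr))
        dm = build_design_matrix(ev["onset"].to_numpy(), n_tr, tr=tr,
                                 event_ids=ev["event_id"].tolist(),
                                 add_drift=False)
        out["designs"][run] = dm
        X_ev = dm.matrix[:, : dm.n_events]
        for name, pset in patterns.items():
            series = X_ev @ pset.data[mask]
            if noise_sd > 0:
                series = series + noise_sd * rng.standard_normal(series.shape)
            out.setdefault(name, {})[run] = series
    return out


@dataclass
class SubjectData:
    """One simulated subject: design, behavior, latents, patterns."""

    subject: int
    design: SessionDesign
    trials: pd.DataFrame
    latents: pd.DataFrame
    patterns: dict


def simulate_subject(spec: DesignSpec, gparams: GenerativeParams,
                     nparams: NeuralParams, seed, subject: int = 0,
                     with_patterns: bool = True) -> SubjectData:
    """Simulate one subject end to end with deterministic sub-streams."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(subject),))
    s_design, s_lat, s_beh, s_pat, s_xs = ss.spawn(5)
    design = generate_design(spec, s_design)
    latents = generate_latents(design, nparams, s_lat)
    gain = latents["gain"].to_numpy()
    # shared subject latent linking hippocampal similarity and behavior
    z_subject = float(np.random.default_rng(s_xs).standard_normal())
    trials = generate_behavior(
        design, gparams, s_beh, block_gain=gain,
        acc_contextual_shift=gparams.xs_acc_slope * z_subject)
    patterns = (generate_patterns(
        design, trials, nparams, s_pat, latents=latents,
        hippo_rho_shift=nparams.xs_hippo_sd * z_subject)
        if with_patterns else {})
    return SubjectData(subject=subject, design=design, trials=trials,
                       latents=latents, patterns=patterns)


def simulate_group(n_subjects: int, spec: DesignSpec,
                   gparams: GenerativeParams, nparams: NeuralParams,
                   seed, with_patterns: bool = True) -> list:
    """Simulate a group; subject streams derive from (seed, subject index)."""
    return [simulate_subject(spec, gparams, nparams, seed, subject=s,
                             with_patterns=with_patterns)
            for s in range(n_subjects)]
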