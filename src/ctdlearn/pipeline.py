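"""End-to-end orchestration: simulate, fit, analyze, summarize.

``run_pipeline`` chains the stages on an in-memory group of simulated
subjects and, when an output directory is configured, writes each stage's
tables (events TSV, pattern HDF5, per-subject and group TSVs, a group
summary JSON and a line-oriented log).  Because every stage is a
deterministic function of (config, seed), running a single stage
regenerates its inputs from the seed bit-identically rather than parsing
rounded TSVs back in.

``calibration_suite`` reruns the group-level tests over many replicate
datasets under the planted-effect and null generators and reports rejection
rates with binomial confidence intervals — the operating characteristics of
every test the pipeline reports.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import brainbehavior as bb
from . import similarity as sim
from .design import DesignSpec, Timings
from .glm import CONTEXT_ONSET, roi_univariate
from .io import write_events_tsv, write_patterns_h5
from .rl import LearnerParams, grid_search_alphas, run_contextual_model, \
    run_temporal_model
from .stats import GroupStats, one_sample_t
from .synth import GenerativeParams, NeuralParams, ROIParams, SubjectData, \
    simulate_group

STAGES = ("simulate", "fit-behavior", "similarity", "coupling", "report")


def _from_dict(cls, d: dict):
    """Build a (nested) dataclass from a dict, rejecting unknown keys."""
    names = {f.name: f for f in fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in d.items():
        if isinstance(val, dict) and key in _NESTED:
            kwargs[key] = _from_dict(_NESTED[key], val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs; schema-validated, unknown keys
    rejected by ``PipelineConfig.from_dict``."""

    n_subjects: int = 33
    seed: int = 0
    out_dir: str | None = None
    design: DesignSpec = field(default_factory=DesignSpec)
    generative: GenerativeParams = field(default_factory=GenerativeParams)
    neural: NeuralParams = field(default_factory=NeuralParams)
    cortical_roi: str = "dlpfc"
    hippocampal_roi: str = "hippocampus"
    sd_mult: float = 2.5
    shrinkage: float = 0.1
    drop_first_run: bool = True
    grid_step: float = 0.01
    use_fitted_alphas: bool = True
    contrast_weights: tuple = (1.0, -1.0, 1.0, -1.0, -2.0, 2.0)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d)

    def contrast(self) -> sim.ContrastSpec:
        return sim.ContrastSpec(tuple(self.contrast_weights))


def _neural_from_dict(d: dict) -> NeuralParams:
    d = dict(d)
    rois = d.pop("rois", None)
    np_kwargs = d
    unknown = set(np_kwargs) - {f.name for f in fields(NeuralParams)}
    if unknown:
        raise ValueError(f"unknown NeuralParams keys: {sorted(unknown)}")
    params = NeuralParams(**np_kwargs) if rois is None else NeuralParams(
        rois={name: _from_dict(ROIParams, spec) for name, spec in rois.items()},
        **np_kwargs)
    return params


_NESTED = {"design": DesignSpec, "generative": GenerativeParams,
           "timings": Timings}


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (JSON/YAML payload)."""
    d = dict(d)
    neural = d.pop("neural", None)
    cfg = _from_dict(PipelineConfig, d)
    if neural is not None:
        cfg = replace(cfg, neural=_neural_from_dict(neural))
    return cfg


# ---------------------------------------------------------------------------
# per-subject analysis


def fit_subject_behavior(sub: SubjectData, config: PipelineConfig) -> dict:
    """Filter trials, fit learning rates by grid search, compute PE series
    and the two behavioral regressions for one subject."""
    trials = sub.trials
    tasks = trials["task"].to_numpy()
    contexts = trials["context"].to_numpy()
    log_rt = np.log(trials["rt_ms"].to_numpy())
    report = beh.filter_trials(trials, sd_mult=config.sd_mult)

    if config.use_fitted_alphas:
        grid = np.round(np.arange(0.01, 0.995, config.grid_step), 10)
        gs = grid_search_alphas(tasks, contexts, log_rt, report.included,
                                grid=grid)
        a_t, a_c = gs.alpha_temporal, gs.alpha_contextual
    else:
        gs = None
        a_t = config.generative.true_alpha_temporal
        a_c = config.generative.true_alpha_contextual

    ser_t = run_temporal_model(tasks, LearnerParams(a_t))
    ser_c = run_contextual_model(tasks, contexts, LearnerParams(a_c))
    pe_t, pe_c = ser_t.pe, ser_c.pe
    inc = report.included
    rt_res = beh.fit_rt_model(log_rt[inc], pe_t[inc], pe_c[inc], tasks[inc])
    acc_res = beh.fit_accuracy_model(trials["accuracy"].to_numpy(),
                                     pe_t, pe_c, tasks)
    series = trials[["run", "block", "trial", "context", "task",
                     "congruent", "accuracy", "post_error"]].copy()
    series["log_rt"] = log_rt
    series["included"] = inc
    series["p_temporal"] = ser_t.prediction
    series["pe_temporal"] = pe_t
    series["p_contextual"] = ser_c.prediction
    series["pe_contextual"] = pe_c
    return dict(subject=sub.subject, alphas=(a_t, a_c), grid=gs,
                report=report, rt=rt_res, accuracy=acc_res, series=series)


def analyze_subject_similarity(sub: SubjectData, config: PipelineConfig,
                               included: np.ndarray) -> dict:
    """All pattern-similarity quantities for one subject.

    ``included``: behavioral inclusion flags aligned with the trial table,
    mapped to trial-cue events before pairing.
    """
    cortex = sub.patterns[config.cortical_roi]
    hippo = sub.patterns[config.hippocampal_roi]
    ev = cortex.events
    runs_all = sorted(ev["run"].unique())
    runs = runs_all[1:] if config.drop_first_run else runs_all

    # map trial inclusion flags onto the event table
    tr = sub.trials
    inc_by_key = dict(zip(zip(tr["run"], tr["block"], tr["trial"]),
                          np.asarray(included, dtype=bool)))
    ev_keys = list(zip(ev["run"], ev["block"], ev["trial"]))
    include_trials = np.array([inc_by_key.get(k, True) for k in ev_keys])

    ct = sim.context_trial_similarity(cortex, runs=runs,
                                      include_trials=include_trials)
    cells = sim.cell_means(ct)
    contrast = sim.reinstatement_contrast(cells, config.contrast())
    cong = {s: sim.congruency_effect(cells, s)
            for s in ("same_pooled", "same_ctd", "different_ctd")}
    trial_reinst = sim.trial_reinstatement(ct)
    block_reinst = sim.block_reinstatement(ct)
    cc_hippo = sim.context_context_similarity(hippo)  # all runs
    hippo_blocks = bb.block_level_similarity(cc_hippo)

    is_ctx = (ev["event_class"] == CONTEXT_ONSET).to_numpy()
    idx = pd.MultiIndex.from_arrays(
        [ev["run"][is_ctx], ev["block"][is_ctx]], names=["run", "block"])
    hippo_uni = pd.Series(roi_univariate(hippo.data[is_ctx]), index=idx)
    cortex_uni_blocks = pd.Series(roi_univariate(cortex.data[is_ctx]),
                                  index=idx)
    cortex_uni_events = pd.Series(roi_univariate(cortex.data),
                                  index=ev["event_id"])
    return dict(subject=sub.subject, ct=ct, cells=cells, contrast=contrast,
                congruency=cong, trial_reinst=trial_reinst,
                block_reinst=block_reinst, cc_hippo=cc_hippo,
                hippo_blocks=hippo_blocks, hippo_uni=hippo_uni,
                cortex_uni_blocks=cortex_uni_blocks,
                cortex_uni_events=cortex_uni_events)


def analyze_subject_coupling(sub: SubjectData, behavior_fit: dict,
                             simres: dict, config: PipelineConfig) -> dict:
    """Brain-behavior regressions for one subject."""
    series = behavior_fit["series"]
    ev = sub.patterns[config.cortical_roi].events
    trial_ev = ev[ev["trial"] >= 0].set_index(["run", "block", "trial"])
    keys = list(zip(series["run"], series["block"], series["trial"]))
    event_id = trial_ev["event_id"].reindex(keys).to_numpy()

    df = series.copy()
    df["event_id"] = event_id
    df["reinstatement"] = simres["trial_reinst"]["value"] \
        .reindex(event_id).to_numpy()
    df["roi_univariate"] = simres["cortex_uni_events"] \
        .reindex(event_id).to_numpy()
    retained = df[df["included"]]
    trial_rt = bb.trial_rt_regression(retained)
    trial_rt_ctx = bb.trial_rt_regression(retained,
                                          include_contextual_pe=True)
    coupling = bb.block_coupling_regression(
        simres["block_reinst"], simres["hippo_blocks"],
        simres["hippo_uni"], simres["cortex_uni_blocks"])
    hippo_rt = bb.hippo_rt_regression(
        retained[["run", "block", "log_rt", "congruent", "pe_temporal",
                  "task"]],
        simres["hippo_blocks"], simres["hippo_uni"])
    return dict(subject=sub.subject, trial_rt=trial_rt,
                trial_rt_ctx=trial_rt_ctx, coupling=coupling,
                hippo_rt=hippo_rt)


# ---------------------------------------------------------------------------
# group pipeline


def _coef_frame(results: list, key: str) -> pd.DataFrame:
    rows = {}
    for r in results:
        res = r[key]
        if getattr(res, "converged", True):
            rows[r["subject"]] = res.coefficients
    return pd.DataFrame(rows).T


@dataclass
class PipelineResult:
    config: PipelineConfig
    subjects: list
    behavior: list
    similarity: list
    coupling: list
    summary: dict


def _test_dict(res) -> dict:
    return dict(t=res.statistic, df=res.df, p=res.p, d=res.d,
                mean=res.mean, sem=res.sem)


def _group_table_dict(gs: GroupStats) -> dict:
    return {name: dict(mean=row["mean"], sem=row["sem"], t=row["t"],
                       p=row["p"], d=row["d"], q=row["q"])
            for name, row in gs.table.iterrows()}


def run_pipeline(config: PipelineConfig, stages=None, log=print) -> PipelineResult:
    """Run the pipeline (all stages by default) and write artifacts when
    ``config.out_dir`` is set.  Individual stages recompute their inputs
    deterministically from the seed."""
    stages = list(STAGES if stages is None else stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def _log(msg):
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log_lines.append(line)
        if log:
            log(line)

    t0 = time.time()
    _log(f"simulating {config.n_subjects} subjects (seed {config.seed})")
    subjects = simulate_group(config.n_subjects, config.design,
                              config.generative, config.neural, config.seed)
    if out and "simulate" in stages:
        write_events_tsv({s.subject: s.trials for s in subjects},
                         out / "events.tsv")
        write_patterns_h5({s.subject: s.patterns for s in subjects},
                          out / "patterns.h5")
        pd.concat([s.latents.assign(subject=s.subject) for s in subjects]) \
            .to_csv(out / "latents.tsv", sep="\t", index=False)
    _log(f"simulation done ({time.time() - t0:.1f}s)")

    behavior_fits, sim_results, coup_results = [], [], []
    summary: dict = dict(config=dict(n_subjects=config.n_subjects,
                                     seed=config.seed))
    need_behavior = bool({"fit-behavior", "coupling", "report"} & set(stages))
    if need_behavior:
        for sub in subjects:
            behavior_fits.append(fit_subject_behavior(sub, config))
        rt_coefs = _coef_frame(behavior_fits, "rt")
        acc_coefs = _coef_frame(behavior_fits, "accuracy")
        family = ["pe_temporal", "pe_contextual"]
        rt_group = beh.group_inference(rt_coefs[family])
        acc_group = beh.group_inference(acc_coefs[family])
        summary["behavior"] = dict(
            rt=_group_table_dict(rt_group), accuracy=_group_table_dict(acc_group),
            alphas=dict(
                temporal=[b["alphas"][0] for b in behavior_fits],
                contextual=[b["alphas"][1] for b in behavior_fits]))
        if out and "fit-behavior" in stages:
            pd.concat([b["series"].assign(subject=b["subject"])
                       for b in behavior_fits]) \
                .to_csv(out / "trials_analysis.tsv", sep="\t", index=False)
            pd.DataFrame(dict(
                subject=[b["subject"] for b in behavior_fits],
                alpha_temporal=[b["alphas"][0] for b in behavior_fits],
                alpha_contextual=[b["alphas"][1] for b in behavior_fits])) \
                .to_csv(out / "alphas.tsv", sep="\t", index=False)
            rt_coefs.rename_axis("subject").to_csv(
                out / "rt_coefficients.tsv", sep="\t")
            acc_coefs.rename_axis("subject").to_csv(
                out / "accuracy_coefficients.tsv", sep="\t")
        _log(f"behavior fit done ({time.time() - t0:.1f}s)")

    need_similarity = bool({"similarity", "coupling", "report"} & set(stages))
    if need_similarity:
        for sub, bfit in zip(subjects, behavior_fits):
            sim_results.append(analyze_subject_similarity(
                sub, config, bfit["report"].included))
        contrasts = np.array([r["contrast"] for r in sim_results])
        cong = {s: np.array([r["congruency"][s] for r in sim_results])
                for s in ("same_pooled", "same_ctd", "different_ctd")}
        diff = sim.differentiation_tests(
            {r["subject"]: r["cc_hippo"] for r in sim_results})
        summary["similarity"] = dict(
            interaction=_test_dict(one_sample_t(contrasts)),
            congruency={k: _test_dict(one_sample_t(v))
                        for k, v in cong.items()},
            validation=_test_dict(diff["validation"]),
            differentiation=_test_dict(diff["differentiation"]),
            hippo_condition_means=dict(
                same_ctd=float(diff["per_subject"]["dif_same_ctd"].mean()),
                different_ctd=float(
                    diff["per_subject"]["dif_different_ctd"].mean())))
        if out and "similarity" in stages:
            pd.concat([r["cells"].rename("fisher_z").reset_index()
                       .assign(subject=r["subject"]) for r in sim_results]) \
                .to_csv(out / "similarity_cells.tsv", sep="\t", index=False)
            pd.DataFrame(dict(subject=[r["subject"] for r in sim_results],
                              interaction=contrasts, **cong)) \
                .to_csv(out / "contrasts.tsv", sep="\t", index=False)
            diff["run_profile"].to_csv(out / "hippo_run_profile.tsv",
                                       sep="\t", index=False)
        _log(f"similarity done ({time.time() - t0:.1f}s)")

    if {"coupling", "report"} & set(stages):
        for sub, bfit, simres in zip(subjects, behavior_fits, sim_results):
            coup_results.append(
                analyze_subject_coupling(sub, bfit, simres, config))
        coup_coefs = _coef_frame(coup_results, "coupling")
        trial_rt_coefs = _coef_frame(coup_results, "trial_rt")
        hippo_rt_coefs = _coef_frame(coup_results, "hippo_rt")
        sim_family = [sim.SAME_CONTEXT, sim.SAME_CTD, sim.DIFFERENT_CTD]
        coup_group = GroupStats.from_subject_coefficients(
            coup_coefs.drop(columns=["constant"]), fdr_family=sim_family)
        trial_rt_group = GroupStats.from_subject_coefficients(
            trial_rt_coefs[["reinstatement"]])
        hippo_rt_group = GroupStats.from_subject_coefficients(
            hippo_rt_coefs.drop(columns=["constant"]))
        same_ctd_mean = pd.Series(
            {r["subject"]: r["hippo_blocks"][sim.SAME_CTD].mean()
             for r in sim_results})
        acc_coefs = _coef_frame(behavior_fits, "accuracy")
        common = same_ctd_mean.index.intersection(acc_coefs.index)
        # behavioral CTD modulation strength: the contextual-PE accuracy
        # coefficient, negated so larger = stronger modulation
        try:
            r_xs, p_xs = bb.cross_subject_correlation(
                same_ctd_mean.loc[common].to_numpy(),
                -acc_coefs.loc[common, "pe_contextual"].to_numpy())
            xs = dict(r=r_xs, p=p_xs)
        except ValueError as exc:
            xs = dict(r=float("nan"), p=float("nan"), note=str(exc))
        summary["coupling"] = _group_table_dict(coup_group)
        summary["trial_rt"] = _group_table_dict(trial_rt_group)
        summary["hippo_rt"] = _group_table_dict(hippo_rt_group)
        summary["cross_subject"] = xs
        if out and "coupling" in stages:
            coup_coefs.rename_axis("subject").to_csv(
                out / "coupling_coefficients.tsv", sep="\t")
            trial_rt_coefs.rename_axis("subject").to_csv(
                out / "trial_rt_coefficients.tsv", sep="\t")
            hippo_rt_coefs.rename_axis("subject").to_csv(
                out / "hippo_rt_coefficients.tsv", sep="\t")
        _log(f"coupling done ({time.time() - t0:.1f}s)")

    if out:
        (out / "group_summary.json").write_text(
            json.dumps(summary, indent=2, default=float) + "\n")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(config=config, subjects=subjects,
                          behavior=behavior_fits, similarity=sim_results,
                          coupling=coup_results, summary=summary)


# ---------------------------------------------------------------------------
# calibration


def replicate_pvalues(config: PipelineConfig, seed: int) -> dict:
    """Group-test (p, t) pairs for one replicate dataset.

    A lean path for calibration: learners run at the true rates and only
    the quantities entering the calibrated tests are computed (no grid
    search, no logistic fits, no trial-level RT regressions).
    """
    cfg = replace(config, seed=seed, use_fitted_alphas=False, out_dir=None)
    subjects = simulate_group(cfg.n_subjects, cfg.design, cfg.generative,
                              cfg.neural, cfg.seed)
    g = cfg.generative
    rt_t, rt_c, contrasts = [], [], []
    coup_h, coup_u = [], []
    cc_by_subj = {}
    for sub in subjects:
        trials = sub.trials
        tasks = trials["task"].to_numpy()
        report = beh.filter_trials(trials, sd_mult=cfg.sd_mult)
        inc = report.included
        pe_t = run_temporal_model(
            tasks, LearnerParams(g.true_alpha_temporal)).pe
        pe_c = run_contextual_model(
            tasks, trials["context"].to_numpy(),
            LearnerParams(g.true_alpha_contextual)).pe
        res = beh.fit_rt_model(np.log(trials["rt_ms"].to_numpy()[inc]),
                               pe_t[inc], pe_c[inc], tasks[inc])
        rt_t.append(res.coefficients["pe_temporal"])
        rt_c.append(res.coefficients["pe_contextual"])

        cortex = sub.patterns[cfg.cortical_roi]
        hippo = sub.patterns[cfg.hippocampal_roi]
        ev = cortex.events
        runs = sorted(ev["run"].unique())
        runs = runs[1:] if cfg.drop_first_run else runs
        tr = trials
        inc_by_key = dict(zip(zip(tr["run"], tr["block"], tr["trial"]), inc))
        keys = list(zip(ev["run"], ev["block"], ev["trial"]))
        include_trials = np.array([inc_by_key.get(k, True) for k in keys])
        ct = sim.context_trial_similarity(cortex, runs=runs,
                                          include_trials=include_trials)
        contrasts.append(sim.reinstatement_contrast(sim.cell_means(ct),
                                                    cfg.contrast()))
        cc = sim.context_context_similarity(hippo)
        cc_by_subj[sub.subject] = cc
        is_ctx = (ev["event_class"] == CONTEXT_ONSET).to_numpy()
        idx = pd.MultiIndex.from_arrays(
            [ev["run"][is_ctx], ev["block"][is_ctx]], names=["run", "block"])
        hippo_uni = pd.Series(roi_univariate(hippo.data[is_ctx]), index=idx)
        cortex_uni = pd.Series(roi_univariate(cortex.data[is_ctx]), index=idx)
        coup = bb.block_coupling_regression(
            sim.block_reinstatement(ct), bb.block_level_similarity(cc),
            hippo_uni, cortex_uni)
        coup_h.append(coup.coefficients[sim.SAME_CTD])
        coup_u.append(coup.coefficients["hippo_univariate"])
    diff = sim.differentiation_tests(cc_by_subj, run_profile=False)
    res_t, res_c = one_sample_t(rt_t), one_sample_t(rt_c)
    res_i = one_sample_t(contrasts)
    res_h, res_u = one_sample_t(coup_h), one_sample_t(coup_u)
    d = diff["differentiation"]
    return dict(
        rt_pe_temporal=(res_t.p, res_t.statistic),
        rt_pe_contextual=(res_c.p, res_c.statistic),
        interaction=(res_i.p, res_i.statistic),
        differentiation=(d.p, d.statistic),
        coupling_same_ctd=(res_h.p, res_h.statistic),
        coupling_hippo_uni=(res_u.p, res_u.statistic),
    )


def null_config(config: PipelineConfig) -> PipelineConfig:
    """Config with every planted effect removed (behavioral betas zero,
    no reinstatement, no hippocampal differentiation or coupling)."""
    gen = replace(config.generative, beta_temporal_pe=0.0,
                  beta_contextual_pe=0.0, beta_temporal_pe_sd=0.0,
                  beta_contextual_pe_sd=0.0, beta_reinstatement=0.0,
                  beta_reinstatement_sd=0.0, acc_beta_temporal=0.0,
                  acc_beta_contextual=0.0, acc_beta_temporal_sd=0.0,
                  acc_beta_contextual_sd=0.0, xs_acc_slope=0.0)
    return replace(config, generative=gen, neural=config.neural.null())


# planted direction of each calibrated group test
TEST_DIRECTIONS = dict(rt_pe_temporal=+1, rt_pe_contextual=+1,
                       interaction=+1, differentiation=-1,
                       coupling_same_ctd=+1, coupling_hippo_uni=+1)


def calibration_suite(config: PipelineConfig, n_replicates: int,
                      seed: int = 0, alpha: float = 0.05,
                      conditions=("planted", "null")) -> pd.DataFrame:
    """Rejection rates of the group tests under planted and null generators.

    Returns one row per (test, condition) with the rejection rate at the
    ``alpha`` level, the rate of rejections whose sign matches the planted
    direction (``rate_directional``), and a Wilson binomial confidence
    interval for the plain rate.
    """
    from statsmodels.stats.proportion import proportion_confint

    configs = {}
    if "planted" in conditions:
        configs["planted"] = config
    if "null" in conditions:
        configs["null"] = null_config(config)
    rows = []
    for cond, cfg in configs.items():
        rejections: dict = {}
        directional: dict = {}
        for rep in range(n_replicates):
            ps = replicate_pvalues(cfg, seed=seed + 1000 * (rep + 1))
            for test, (p, t) in ps.items():
                rejections.setdefault(test, []).append(p < alpha)
                directional.setdefault(test, []).append(
                    p < alpha and np.sign(t) == TEST_DIRECTIONS[test])
        for test, rej in rejections.items():
            k, m = int(np.sum(rej)), len(rej)
            lo, hi = proportion_confint(k, m, method="wilson")
            rows.append(dict(test=test, condition=cond, n_replicates=m,
                             rejections=k, rate=k / m,
                             rate_directional=float(
                                 np.mean(directional[test])),
                             ci_low=float(lo), ci_high=float(hi)))
    return pd.DataFrame(rows)


def alpha_recovery_experiment(config: PipelineConfig, n_subjects: int,
                              seed: int) -> pd.DataFrame:
    """Per-subject grid-search learning-rate estimates at the planted truth.

    Simulates ``n_subjects`` (behavior only), applies the RT filters, runs
    the full 0.01-step grid search and returns a frame with the estimates
    and absolute errors against the generative rates.
    """
    g = config.generative
    subjects = simulate_group(n_subjects, config.design, g, config.neural,
                              seed, with_patterns=False)
    rows = []
    for sub in subjects:
        tr = sub.trials
        rep = beh.filter_trials(tr, sd_mult=config.sd_mult)
        gs = grid_search_alphas(tr["task"].to_numpy(),
                                tr["context"].to_numpy(),
                                np.log(tr["rt_ms"].to_numpy()),
                                rep.included)
        rows.append(dict(subject=sub.subject,
                         alpha_temporal=gs.alpha_temporal,
                         alpha_contextual=gs.alpha_contextual,
                         err_temporal=abs(gs.alpha_temporal
                                          - g.true_alpha_temporal),
                         err_contextual=abs(gs.alpha_contextual
                                            - g.true_alpha_contextual)))
    return pd.DataFrame(rows)


def recovery_config(config: PipelineConfig) -> PipelineConfig:
    """Config for coefficient-recovery experiments: the reinstatement RT
    channel is switched off so the planted PE coefficients are the complete
    generative truth for the behavioral regression."""
    gen = replace(config.generative, beta_reinstatement=0.0,
                  beta_reinstatement_sd=0.0)
    return replace(config, generative=gen)


def rt_coefficient_recovery(config: PipelineConfig, seed: int,
                            n_subjects: int | None = None) -> dict:
    """Group-level recovery of the planted RT coefficients (PEs computed at
    the true learning rates; reinstatement channel off)."""
    cfg = recovery_config(config)
    n = n_subjects or cfg.n_subjects
    g = cfg.generative
    subjects = simulate_group(n, cfg.design, g, cfg.neural, seed,
                              with_patterns=False)
    rows = []
    for sub in subjects:
        tr = sub.trials
        rep = beh.filter_trials(tr, sd_mult=cfg.sd_mult)
        inc = rep.included
        tasks = tr["task"].to_numpy()
        pe_t = run_temporal_model(tasks,
                                  LearnerParams(g.true_alpha_temporal)).pe
        pe_c = run_contextual_model(tasks, tr["context"].to_numpy(),
                                    LearnerParams(g.true_alpha_contextual)).pe
        res = beh.fit_rt_model(np.log(tr["rt_ms"].to_numpy()[inc]),
                               pe_t[inc], pe_c[inc], tasks[inc])
        rows.append(res.coefficients)
    coefs = pd.DataFrame(rows)
    out = {}
    for name, truth in (("pe_temporal", g.beta_temporal_pe),
                        ("pe_contextual", g.beta_contextual_pe)):
        res = one_sample_t(coefs[name])
        out[name] = dict(mean=res.mean, sem=res.sem, truth=truth,
                         bias_in_sems=abs(res.mean - truth) / res.sem)
    return out


def permuted_rt_null(config: PipelineConfig, n_replicates: int, seed: int,
                     alpha: float = 0.05) -> dict:
    """False-positive rate of the group PE tests on permuted RTs.

    Each replicate simulates a fresh group, permutes every subject's
    log-RTs across their included trials (destroying any RT-PE association
    while keeping the predictor structure) and refits the regressions, so
    the binomial confidence interval on the rejection rate is valid
    unconditionally.
    """
    from statsmodels.stats.proportion import proportion_confint

    cfg = recovery_config(config)
    g = cfg.generative
    rng = np.random.default_rng(seed)
    rej = {"pe_temporal": [], "pe_contextual": []}
    for rep in range(n_replicates):
        subjects = simulate_group(cfg.n_subjects, cfg.design, g, cfg.neural,
                                  seed + 1000 * (rep + 1),
                                  with_patterns=False)
        coefs = {"pe_temporal": [], "pe_contextual": []}
        for sub in subjects:
            tr = sub.trials
            inc = beh.filter_trials(tr, sd_mult=cfg.sd_mult).included
            tasks = tr["task"].to_numpy()
            pe_t = run_temporal_model(
                tasks, LearnerParams(g.true_alpha_temporal)).pe
            pe_c = run_contextual_model(
                tasks, tr["context"].to_numpy(),
                LearnerParams(g.true_alpha_contextual)).pe
            y = rng.permutation(np.log(tr["rt_ms"].to_numpy()[inc]))
            res = beh.fit_rt_model(y, pe_t[inc], pe_c[inc], tasks[inc])
            for k in coefs:
                coefs[k].append(res.coefficients[k])
        for k in coefs:
            rej[k].append(one_sample_t(coefs[k]).p < alpha)
    out = {}
    for k, flags in rej.items():
        kk, m = int(np.sum(flags)), len(flags)
        lo, hi = proportion_confint(kk, m, method="wilson")
        out[k] = dict(rate=kk / m, n=m, ci_low=float(lo), ci_high=float(hi))
    return out
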