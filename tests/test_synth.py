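import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from ctdlearn.behavior import quintile_summary
from ctdlearn.design import DesignSpec, generate_design
from ctdlearn.glm import CONTEXT_ONSET, fit_event_glm
from ctdlearn.similarity import (cell_means, context_trial_similarity,
                                 reinstatement_contrast)
from ctdlearn.stats import ols_fit
from ctdlearn.synth import (GenerativeParams, NeuralParams, ROIParams,
                            generate_behavior, generate_latents,
                            generate_patterns, generate_timeseries,
                            simulate_subject)
from ctdlearn.rl import LearnerParams, run_contextual_model, \
    run_temporal_model


def _noiseless_roi(**kw):
    base = dict(n_voxels=40, noise_sd=0.0, amp_fluct_sd=0.0)
    base.update(kw)
    return ROIParams(**base)


class TestGenerateBehavior:
    def test_strong_negative_contextual_effect_orders_quintiles(self, design):
        params = replace(GenerativeParams(), acc_intercept=0.0,
                         acc_beta_temporal=0.0, acc_beta_contextual=-8.0,
                         acc_beta_task=0.0, acc_beta_temporal_sd=0.0,
                         acc_beta_contextual_sd=0.0, xs_acc_slope=0.0,
                         rt_noise_sd=1e-9)
        trials = generate_behavior(design, params, seed=3)
        pe_c = run_contextual_model(trials["task"].to_numpy(),
                                    trials["context"].to_numpy(),
                                    LearnerParams(0.10)).pe
        bins = quintile_summary(trials["accuracy"].to_numpy(), pe_c)
        assert np.all(np.diff(bins) <= 0)
        assert bins[0] > bins[-1]

    def test_null_betas_recovered_as_zero(self, design):
        params = replace(GenerativeParams(), beta_temporal_pe=0.0,
                         beta_contextual_pe=0.0, beta_temporal_pe_sd=0.0,
                         beta_contextual_pe_sd=0.0, beta_reinstatement=0.0,
                         rt_noise_sd=1e-8)
        trials = generate_behavior(design, params, seed=4)
        tasks = trials["task"].to_numpy()
        pe_t = run_temporal_model(tasks, LearnerParams(0.30)).pe
        pe_c = run_contextual_model(tasks, trials["context"].to_numpy(),
                                    LearnerParams(0.10)).pe
        X = np.column_stack([pe_t, pe_c, tasks, np.ones(len(tasks))])
        res = ols_fit(np.log(trials["rt_ms"].to_numpy()), X,
                      ["pe_t", "pe_c", "task", "c"])
        assert res.coefficients["pe_t"] == pytest.approx(0.0, abs=1e-6)
        assert res.coefficients["pe_c"] == pytest.approx(0.0, abs=1e-6)

    def test_post_error_flags_follow_errors_within_block(self, design):
        trials = generate_behavior(design, GenerativeParams(), seed=5)
        acc = trials["accuracy"].to_numpy()
        post = trials["post_error"].to_numpy()
        blocks = list(zip(trials["run"], trials["block"]))
        for i in range(1, len(trials)):
            expected = (acc[i - 1] == 0) and (blocks[i] == blocks[i - 1])
            assert post[i] == expected
        assert not post[0]

    def test_deterministic_given_seed(self, design):
        a = generate_behavior(design, GenerativeParams(), seed=6)
        b = generate_behavior(design, GenerativeParams(), seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestGeneratePatterns:
    def test_noiseless_same_ctd_pair_correlation_matches_target(self):
        """With zero voxel noise and no reinstatement gain, the sample
        correlation between two room-onset patterns of rooms sharing a CTD
        equals the planted target exactly (construction oracle)."""
        spec = DesignSpec(n_runs=1)
        design = generate_design(spec, seed=0)
        rho = 0.37
        nparams = NeuralParams(
            rois={"roi": _noiseless_roi(reinstatement=False, overlap_sd=0.0,
                                        rho_same_ctd=rho, rho_diff_ctd=0.11)},
            gain0=0.0, gamma_h=0.0, gamma_u=0.0, gain_noise_sd=0.0,
            xs_hippo_sd=0.0)
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        pats = generate_patterns(design, trials, nparams, seed=2)["roi"]
        ev = pats.events
        ctx_onsets = ev[ev["event_class"] == CONTEXT_ONSET]
        by_context = {c: pats.data[g.index[0]]
                      for c, g in ctx_onsets.groupby("context")}
        ctd = spec.ctd_assignment
        for a in range(4):
            for b in range(a + 1, 4):
                r = np.corrcoef(by_context[a], by_context[b])[0, 1]
                expect = rho if ctd[a] == ctd[b] else 0.11
                assert r == pytest.approx(expect, abs=1e-6)

    def test_planted_rho_ordering_reproduced_empirically(self, design):
        """Monte-Carlo check at small noise: planted same-CTD below
        different-CTD shows up in the empirical cross-run similarity."""
        nparams = NeuralParams(
            rois={"roi": _noiseless_roi(reinstatement=False,
                                        rho_same_ctd=0.1, rho_diff_ctd=0.5,
                                        noise_sd=0.05)},
            xs_hippo_sd=0.0)
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        pats = generate_patterns(design, trials, nparams, seed=9)["roi"]
        from ctdlearn.similarity import condition_means, \
            context_context_similarity
        means = condition_means(context_context_similarity(pats))
        assert means["same_ctd"] < means["different_ctd"]
        assert means["same_context"] > means["different_ctd"]

    def test_zero_gain_kills_the_interaction_contrast_exactly(self, design):
        nparams = NeuralParams(
            rois={"roi": _noiseless_roi(reinstatement=True)},
            gain0=0.0, gamma_h=0.0, gamma_u=0.0, gain_noise_sd=0.0)
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        pats = generate_patterns(design, trials, nparams, seed=3)["roi"]
        cells = cell_means(context_trial_similarity(pats))
        assert reinstatement_contrast(cells) == pytest.approx(0.0, abs=1e-10)

    def test_non_psd_target_raises_configuration_error(self, design):
        nparams = NeuralParams(rois={"roi": ROIParams(rho_same_ctd=-0.9,
                                                      rho_diff_ctd=0.9)})
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_patterns(design, trials, nparams, seed=0)

    def test_determinism_byte_identical(self, spec, gparams, nparams):
        a = simulate_subject(spec, gparams, nparams, seed=11, subject=2)
        b = simulate_subject(spec, gparams, nparams, seed=11, subject=2)
        assert a.trials.equals(b.trials)
        for roi in a.patterns:
            assert np.array_equal(a.patterns[roi].data, b.patterns[roi].data)

    def test_subject_streams_differ(self, spec, gparams, nparams):
        a = simulate_subject(spec, gparams, nparams, seed=11, subject=0)
        b = simulate_subject(spec, gparams, nparams, seed=11, subject=1)
        assert not np.array_equal(a.patterns["dlpfc"].data,
                                  b.patterns["dlpfc"].data)


@pytest.fixture
def small_session():
    spec = DesignSpec(n_runs=1, n_blocks_per_run=4)
    design = generate_design(spec, seed=0)
    nparams = NeuralParams(rois={"roi": _noiseless_roi()},
                           gain_noise_sd=0.0)
    trials = generate_behavior(design, GenerativeParams(), seed=1)
    patterns = generate_patterns(design, trials, nparams, seed=2)
    return design, nparams, patterns


class TestGenerateTimeseries:
    def test_single_event_series_is_pattern_times_hrf(self):
        spec = DesignSpec(n_runs=1, n_blocks_per_run=4,
                          n_trials_per_block=4)
        design = generate_design(spec, seed=0)
        nparams = NeuralParams(rois={"roi": _noiseless_roi()})
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        patterns = generate_patterns(design, trials, nparams, seed=2)
        # restrict to one event by zeroing all other patterns
        pats = patterns["roi"]
        pats.data[1:] = 0.0
        ts = generate_timeseries(design, patterns, nparams, seed=0)
        dm = ts["designs"][0]
        col = dm.matrix[:, 0]
        expect = np.outer(col, pats.data[0])
        assert ts["roi"][0] == pytest.approx(expect, abs=1e-12)

    def test_glm_refit_recovers_planted_patterns(self, small_session):
        design, nparams, patterns = small_session
        ts = generate_timeseries(design, patterns, nparams, seed=0)
        dm = ts["designs"][0]
        betas, _ = fit_event_glm(ts["roi"][0], dm)
        mask = (patterns["roi"].events["run"] == 0).to_numpy()
        assert betas == pytest.approx(patterns["roi"].data[mask], abs=1e-6)

    def test_glm_refit_with_overlapping_events_still_exact(self):
        # trials 6 s apart: HRF responses overlap heavily but the design
        # stays full rank
        spec = DesignSpec(n_runs=1, n_blocks_per_run=4)
        design = generate_design(spec, seed=3)
        nparams = NeuralParams(rois={"roi": _noiseless_roi()})
        trials = generate_behavior(design, GenerativeParams(), seed=1)
        patterns = generate_patterns(design, trials, nparams, seed=2)
        ts = generate_timeseries(design, patterns, nparams, seed=0)
        betas, _ = fit_event_glm(ts["roi"][0], ts["designs"][0])
        assert betas == pytest.approx(patterns["roi"].data, abs=1e-6)


class TestLatents:
    def test_gain_composition(self, design):
        nparams = NeuralParams(gain0=0.5, gamma_h=0.2, gamma_u=0.3,
                               gain_noise_sd=0.0)
        lat = generate_latents(design, nparams, seed=0)
        expect = 0.5 + 0.2 * lat["hippo_overlap"] + 0.3 * lat["hippo_amp"]
        assert lat["gain"].to_numpy() == pytest.approx(expect.to_numpy())

    def test_null_generator_removes_every_planted_effect(self, nparams):
        null = nparams.null()
        assert null.gain0 == 0 and null.gamma_h == 0 and null.gamma_u == 0
        assert null.xs_hippo_sd == 0
        for roi in null.rois.values():
            assert np.isscalar(roi.rho_same_ctd)
            assert roi.rho_same_ctd == roi.rho_diff_ctd
            assert roi.overlap_sd == 0
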