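import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctdlearn.design import DesignSpec
from ctdlearn.glm import CONTEXT_ONSET, TRIAL_CUE
from ctdlearn.similarity import (CELL_ORDER, DIFFERENT_CTD, SAME_CONTEXT,
                                 SAME_CTD, ContrastSpec, block_reinstatement,
                                 cell_means, congruency_effect,
                                 context_context_similarity,
                                 context_trial_similarity,
                                 differentiation_tests, fisher_pearson,
                                 label_pair, reinstatement_contrast,
                                 trial_reinstatement)


class TestFisherPearson:
    def test_orthogonal_centered_vectors_give_zero(self):
        assert fisher_pearson([1, -1, 1, -1], [1, 1, -1, -1]) == \
            pytest.approx(0.0)

    def test_worked_example_matches_scipy_oracle(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        z = fisher_pearson(x, y)
        r = sps.pearsonr(x, y).statistic
        assert r == pytest.approx(0.98198051)
        assert z == pytest.approx(np.arctanh(r), abs=1e-9)
        assert z == pytest.approx(2.3502, abs=5e-4)

    def test_identical_vectors_clamp(self):
        x = [1.0, 2.0, 5.0]
        assert fisher_pearson(x, x) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_random_vectors_match_scipy(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 17))
            assert fisher_pearson(x, y) == pytest.approx(
                np.arctanh(sps.pearsonr(x, y).statistic), abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            fisher_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLabelPair:
    def test_same_room_congruent(self):
        assert label_pair(0, 1, 0, 1, task_b=1) == (SAME_CONTEXT, True)

    def test_different_rooms_same_ctd_incongruent(self):
        assert label_pair(0, 1, 1, 1, task_b=0) == (SAME_CTD, False)

    def test_opposite_ctd_is_different_regardless_of_task(self):
        for task in (0, 1):
            rel, _ = label_pair(0, 0, 2, 1, task_b=task)
            assert rel == DIFFERENT_CTD

    def test_context_pair_has_no_congruency(self):
        assert label_pair(0, 0, 1, 0) == (SAME_CTD, None)


class TestContrastSpec:
    def test_default_weights_sum_to_zero_and_orthogonal(self):
        w = np.array(ContrastSpec().weights)
        assert w.sum() == 0
        assert w @ np.array([1, -1, 1, -1, 1, -1]) == 0
        assert w @ np.array([1, 1, 1, 1, -2, -2]) == 0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec((1, 1, 1, 1, -2, -2))  # congruency main effect
        with pytest.raises(ValueError):
            ContrastSpec((1, -1, 1, -1, -2, 1))  # not zero-sum


def brute_force_pairs(events_a, events_b, unordered=False):
    pairs = set()
    for (i, ra), (j, rb) in itertools.product(
            zip(events_a.index, events_a["run"]),
            zip(events_b.index, events_b["run"])):
        if ra == rb:
            continue
        if unordered:
            if i >= j:
                continue
        pairs.add((i, j))
    return pairs


class TestPairBookkeeping:
    @pytest.mark.parametrize("n_runs,n_blocks", [(6, 8), (3, 4), (2, 8)])
    def test_context_trial_pair_count_matches_enumeration(
            self, gparams, nparams, n_runs, n_blocks):
        from ctdlearn.synth import simulate_subject
        spec = DesignSpec(n_runs=n_runs, n_blocks_per_run=n_blocks)
        sub = simulate_subject(spec, gparams, nparams, seed=3)
        pset = sub.patterns["dlpfc"]
        runs = sorted(pset.events["run"].unique())[1:]
        tab = context_trial_similarity(pset, runs=runs)
        ev = pset.events
        ctx = ev[(ev["event_class"] == CONTEXT_ONSET) & ev["run"].isin(runs)]
        tri = ev[(ev["event_class"] == TRIAL_CUE) & ev["run"].isin(runs)]
        expect = brute_force_pairs(ctx.set_index("event_id"),
                                   tri.set_index("event_id"))
        got = set(zip(tab["event_a"], tab["event_b"]))
        assert got == expect
        # per context event: out-of-run retained trials
        n_trials_per_run = n_blocks * spec.n_trials_per_block
        per_ctx = (len(runs) - 1) * n_trials_per_run
        assert len(tab) == len(ctx) * per_ctx

    def test_context_context_pair_count_960_for_default_design(
            self, subject):
        tab = context_context_similarity(subject.patterns["hippocampus"])
        # 48 room onsets; cross-run partners per event: 40; unordered
        assert len(tab) == 48 * 40 // 2
        assert (tab["run_a"] != tab["run_b"]).all()
        assert not tab.duplicated(["event_a", "event_b"]).any()

    def test_no_within_run_or_first_run_pairs_in_reinstatement(self, subject):
        pset = subject.patterns["dlpfc"]
        runs = sorted(pset.events["run"].unique())[1:]
        tab = context_trial_similarity(pset, runs=runs)
        assert (tab["run_a"] != tab["run_b"]).all()
        assert (tab["run_a"] != 0).all() and (tab["run_b"] != 0).all()

    def test_identical_patterns_give_clamped_equal_z(self, subject):
        pset = subject.patterns["dlpfc"]
        flat = pset.subset(np.ones(len(pset.events), dtype=bool))
        flat.data = np.tile(flat.data[0], (len(flat.events), 1))
        tab = context_trial_similarity(flat)
        assert np.allclose(tab["fisher_z"], np.arctanh(1 - 1e-7))


def table_from_cells(values):
    """Build a similarity table realizing given per-cell values."""
    rows = []
    for (rel, con), v in zip(CELL_ORDER, values):
        for k in range(2):
            rows.append(dict(event_a=100 + len(rows), event_b=len(rows),
                             run_a=1, run_b=2, block_a=0, block_b=0,
                             relation=rel, congruent=con, fisher_z=v))
    return pd.DataFrame(rows)


class TestCellsAndContrasts:
    def test_cell_means_by_direct_averaging(self):
        tab = table_from_cells([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        cells = cell_means(tab)
        assert cells.to_numpy() == pytest.approx([0.1, 0.2, 0.3, 0.4,
                                                  0.5, 0.6])

    def test_missing_cell_flagged_as_nan(self):
        tab = table_from_cells([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        tab = tab[~((tab["relation"] == SAME_CTD) & tab["congruent"])]
        cells = cell_means(tab)
        assert np.isnan(cells[(SAME_CTD, True)])
        with pytest.raises(ValueError, match="missing"):
            reinstatement_contrast(cells)

    def test_contrast_worked_example(self):
        cells = cell_means(table_from_cells([1, 0, 1, 0, 0, 0]))
        assert reinstatement_contrast(cells) == pytest.approx(2.0)

    def test_equal_cells_give_zero_contrast(self):
        cells = cell_means(table_from_cells([0.3] * 6))
        assert reinstatement_contrast(cells) == pytest.approx(0.0)

    def test_congruency_effect_construction(self):
        # congruency effect delta planted in the same-relation cells only
        delta = 0.25
        cells = cell_means(table_from_cells(
            [0.5 + delta, 0.5, 0.4 + delta, 0.4, 0.2, 0.2]))
        assert congruency_effect(cells, "same_pooled") == \
            pytest.approx(delta)
        assert congruency_effect(cells, "same_ctd") == pytest.approx(delta)
        assert congruency_effect(cells, "different_ctd") == \
            pytest.approx(0.0)

    def test_congruency_effect_is_linear_in_cells(self):
        vals = np.array([0.5, 0.1, 0.4, 0.2, 0.3, 0.6])
        a = congruency_effect(cell_means(table_from_cells(vals)),
                              "same_pooled")
        b = congruency_effect(cell_means(table_from_cells(-vals)),
                              "same_pooled")
        assert b == pytest.approx(-a)


class TestTrialAndBlockReinstatement:
    def test_signed_by_congruency(self):
        tab = pd.DataFrame(dict(
            event_a=[100, 101, 102, 103], event_b=[1, 1, 2, 2],
            run_a=[1, 2, 1, 2], run_b=[3, 3, 3, 3],
            block_a=[0, 0, 1, 1], block_b=[5, 5, 5, 5],
            relation=[SAME_CONTEXT, SAME_CTD, SAME_CONTEXT, SAME_CTD],
            congruent=[True, True, False, False],
            fisher_z=[0.3, 0.5, 0.3, 0.5]))
        tr = trial_reinstatement(tab)
        assert tr.loc[1, "value"] == pytest.approx(0.4)
        assert tr.loc[2, "value"] == pytest.approx(-0.4)

    def test_different_ctd_pairs_are_ignored(self):
        tab = pd.DataFrame(dict(
            event_a=[100, 101], event_b=[1, 1], run_a=[1, 2], run_b=[3, 3],
            block_a=[0, 0], block_b=[5, 5],
            relation=[SAME_CONTEXT, DIFFERENT_CTD],
            congruent=[True, True], fisher_z=[0.3, 99.0]))
        tr = trial_reinstatement(tab)
        assert tr.loc[1, "value"] == pytest.approx(0.3)

    def test_block_value_is_match_minus_mismatch_at_its_onset(self):
        tab = pd.DataFrame(dict(
            event_a=[100, 100, 100], event_b=[1, 2, 3],
            run_a=[1, 1, 1], run_b=[2, 2, 2],
            block_a=[4, 4, 4], block_b=[0, 1, 2],
            relation=[SAME_CTD, SAME_CTD, SAME_CONTEXT],
            congruent=[True, False, True], fisher_z=[0.6, 0.1, 0.4]))
        br = block_reinstatement(tab)
        assert br.loc[(1, 4)] == pytest.approx((0.6 + 0.4) / 2 - 0.1)

    def test_block_missing_a_congruency_cell_is_nan(self):
        tab = pd.DataFrame(dict(
            event_a=[100], event_b=[1], run_a=[1], run_b=[2],
            block_a=[4], block_b=[0], relation=[SAME_CTD],
            congruent=[True], fisher_z=[0.6]))
        assert np.isnan(block_reinstatement(tab).loc[(1, 4)])


class TestDifferentiation:
    def test_planted_ordering_detected_in_group_paired_t(self, gparams,
                                                         nparams):
        from ctdlearn.synth import simulate_subject
        spec = DesignSpec()
        tables = {}
        for s in range(12):
            sub = simulate_subject(spec, gparams, nparams, seed=20,
                                   subject=s)
            tables[s] = context_context_similarity(
                sub.patterns["hippocampus"])
        res = differentiation_tests(tables)
        assert res["differentiation"].statistic < 0  # same CTD < different
        assert res["validation"].statistic > 0       # same context highest
        prof = res["run_profile"]
        assert set(prof["run"]) == set(range(6))

    def test_identical_condition_means_flagged(self):
        tab = pd.DataFrame(dict(
            event_a=[0, 1, 2], event_b=[3, 4, 5], run_a=[0, 0, 0],
            run_b=[1, 1, 1], block_a=[0, 0, 0], block_b=[0, 0, 0],
            relation=[SAME_CONTEXT, SAME_CTD, DIFFERENT_CTD],
            fisher_z=[0.2, 0.2, 0.2]))
        res = differentiation_tests({s: tab for s in range(4)},
                                    differentiation_runs=(0, 1),
                                    run_profile=False)
        assert res["differentiation"].flagged
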