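"""Experimental design generation for the context-task-demand paradigm.

The task embeds perceptual decision-making blocks in four spatial contexts
(rooms).  Each run visits every context an equal number of times; a block
shows the room interior for 7.75 s and then eight trials (task cue 0.25 s,
compound face/object stimulus 1.5 s, 4.25 s inter-trial interval).  Two
contexts are dominated by the face task and two by the object task, with
the dominant task required on 75% of a block's trials — realized exactly
(6 of 8 trials) so the contingency is identical in every block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FACE, OBJECT = 0, 1
TASK_NAMES = {FACE: "face", OBJECT: "object"}


@dataclass(frozen=True)
class Timings:
    """Event timings in seconds within a block."""

    room_duration: float = 7.75
    cue_duration: float = 0.25
    stim_duration: float = 1.5
    iti: float = 4.25

    @property
    def trial_length(self) -> float:
        return self.cue_duration + self.stim_duration + self.iti


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the block/trial design (defaults follow the paradigm)."""

    n_runs: int = 6
    n_blocks_per_run: int = 8
    n_trials_per_block: int = 8
    n_contexts: int = 4
    dominant_prob: float = 0.75
    timings: Timings = field(default_factory=Timings)
    ctd_assignment: tuple = (FACE, FACE, OBJECT, OBJECT)

    def __post_init__(self) -> None:
        if self.n_blocks_per_run % self.n_contexts:
            raise ValueError(
                f"n_contexts ({self.n_contexts}) must divide n_blocks_per_run "
                f"({self.n_blocks_per_run})")
        n_dom = self.dominant_prob * self.n_trials_per_block
        if abs(n_dom - round(n_dom)) > 1e-9:
            raise ValueError(
                f"dominant_prob * n_trials_per_block = {n_dom} is not an "
                "integer; the per-block task split must be exact")
        if len(self.ctd_assignment) != self.n_contexts:
            raise ValueError("ctd_assignment must map every context")
        counts = np.bincount(np.asarray(self.ctd_assignment), minlength=2)
        if counts[FACE] != counts[OBJECT]:
            raise ValueError(
                "exactly half the contexts must map to each task demand, "
                f"got {counts[FACE]} face / {counts[OBJECT]} object")

    @property
    def n_dominant(self) -> int:
        return round(self.dominant_prob * self.n_trials_per_block)

    @property
    def blocks_per_context_per_run(self) -> int:
        return self.n_blocks_per_run // self.n_contexts

    @property
    def block_length(self) -> float:
        t = self.timings
        return t.room_duration + self.n_trials_per_block * t.trial_length


@dataclass(frozen=True)
class SessionDesign:
    """A realized session: block table + trial table (no behavior yet).

    ``blocks`` columns: run, block, context, ctd, room_onset.
    ``trials`` columns: run, block, trial, context, ctd, task, congruent,
    cue_onset.  Onsets are per-run clocks in seconds.
    """

    spec: DesignSpec
    blocks: pd.DataFrame
    trials: pd.DataFrame


def generate_design(spec: DesignSpec, seed: int) -> SessionDesign:
    """Generate block and trial tables for one subject.

    The block -> context sequence is shuffled per run with each context
    appearing exactly ``n_blocks_per_run / n_contexts`` times; within each
    block the exact 6:2 congruent:incongruent trial split is shuffled.
    Identical (spec, seed) yields an identical design.
    """
    rng = np.random.default_rng(seed)
    ctd = np.asarray(spec.ctd_assignment)
    t = spec.timings

    block_rows, trial_rows = [], []
    for run in range(spec.n_runs):
        ctx_seq = np.repeat(np.arange(spec.n_contexts),
                            spec.blocks_per_context_per_run)
        rng.shuffle(ctx_seq)
        for block, ctx in enumerate(ctx_seq):
            room_onset = block * spec.block_length
            dom = ctd[ctx]
            tasks = np.full(spec.n_trials_per_block, 1 - dom)
            tasks[: spec.n_dominant] = dom
            rng.shuffle(tasks)
            block_rows.append(dict(run=run, block=block, context=int(ctx),
                                   ctd=int(dom), room_onset=room_onset))
            for k, task in enumerate(tasks):
                cue_onset = room_onset + t.room_duration + k * t.trial_length
                trial_rows.append(dict(
                    run=run, block=block, trial=k, context=int(ctx),
                    ctd=int(dom), task=int(task),
                    congruent=bool(task == dom), cue_onset=cue_onset))
    blocks = pd.DataFrame(block_rows)
    trials = pd.DataFrame(trial_rows)
    return SessionDesign(spec=spec, blocks=blocks, trials=trials)
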