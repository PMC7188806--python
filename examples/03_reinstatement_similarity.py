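"""Cross-run pattern similarity and the reinstatement interaction contrast.

Simulates one subject's multi-voxel patterns, pairs every room-onset
pattern with out-of-run trial patterns (runs 2-6), averages Fisher-z
similarity in the 3 (context relation) x 2 (congruency) cells and evaluates
the interaction contrast that indexes reinstatement of the contextual task
demand (CTD).
"""

from ctdlearn import (DesignSpec, GenerativeParams, cell_means,
                      congruency_effect, context_trial_similarity,
                      reinstatement_contrast)
from ctdlearn.synth import NeuralParams, simulate_subject

sub = simulate_subject(DesignSpec(), GenerativeParams(), NeuralParams(),
                       seed=3)
ct = context_trial_similarity(sub.patterns["dlpfc"])
cells = cell_means(ct)
print(f"{len(ct)} cross-run context-trial pairs")
print("\ncell means (Fisher z):")
print(cells.round(4))
print(f"\ninteraction contrast: {reinstatement_contrast(cells):.4f}")
for subset in ("same_pooled", "same_ctd", "different_ctd"):
    print(f"congruency effect ({subset}): "
          f"{congruency_effect(cells, subset):+.4f}")
# A positive interaction contrast means room-onset patterns resemble the
# upcoming dominant task's patterns more on congruent than incongruent
# trials when context and trial share a task demand - and the effect
# reverses for different-demand pairs, the signature of CTD reinstatement.
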