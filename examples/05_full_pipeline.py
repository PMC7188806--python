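"""The orchestrated pipeline: simulate -> fit -> similarity -> coupling.

Runs every stage on a reduced configuration and prints the group summary.
The same run is available from the shell:

    ctdlearn run --seed 11 --out out/ --n-subjects 8
"""

import json
from dataclasses import replace

from ctdlearn import NeuralParams, PipelineConfig, run_pipeline
from ctdlearn.synth import default_rois

rois = {name: replace(p, n_voxels=24) for name, p in default_rois().items()}
config = PipelineConfig(n_subjects=8, seed=11,
                        neural=replace(NeuralParams(), rois=rois),
                        grid_step=0.05)
result = run_pipeline(config, log=None)

summary = result.summary
print("group summary (subset):")
print(json.dumps({
    "behavior.rt": {k: round(v["mean"], 4)
                    for k, v in summary["behavior"]["rt"].items()},
    "similarity.interaction.t": round(summary["similarity"]["interaction"]["t"], 2),
    "similarity.differentiation.t": round(
        summary["similarity"]["differentiation"]["t"], 2),
    "coupling.same_ctd.mean": round(summary["coupling"]["same_ctd"]["mean"], 4),
    "cross_subject.r": round(summary["cross_subject"]["r"], 3),
}, indent=2))
# With an output directory configured, each stage also writes TSV/HDF5
# artifacts (events, patterns, per-subject coefficients, group summary).
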