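"""Run the whole correlative analysis on a synthetic experiment.

Generates an interleaved acquisition (conventional cluster channel +
single-molecule PALM channel + bead calibration), then registers, links,
classifies, motion-corrects and quantifies. The printed counts trace every
stage; the metrics table holds per-locus structure after motion correction.
"""

from mcpalm.pipeline import run_pipeline_frames
from mcpalm.simulate import SimulationConfig, simulate_experiment

exp = simulate_experiment(SimulationConfig(seed=1))
res = run_pipeline_frames(exp.sm_locs, exp.cluster_locs, exp.bead_pairs)

print("stage counts:")
for k, v in res.counts.items():
    print(f"  {k}: {v}")

cols = ["cluster_id", "n_localizations", "radius_of_gyration_nm", "area_um2",
        "extension_nm", "localization_density_per_um2_s"]
print("\nper-locus structure (motion-corrected):")
print(res.metrics[cols].round(3).to_string(index=False))

# bound molecules move relative to the locus they sit on: ratio > 1
print("\nrelative mobility of bound molecules vs their locus:")
print(res.relative.round(3).to_string(index=False))

print(
    "\nThe trace classes separate bound dCas9-like probes from searching/"
    "freely diffusing ones by geometry, not by a mobility threshold; the "
    "corrected metrics describe locus structure with the motion removed."
)
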