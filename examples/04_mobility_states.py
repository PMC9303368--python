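"""Why a mobility threshold cannot separate bound from unbound probes.

Fits per-trace diffusion coefficients from TAMSD curves, models the log10-D
distribution with a BIC-selected Gaussian mixture, and measures the overlap
between the bound and unbound populations — then shows that the correlative
(geometric) classification still separates them.
"""

import numpy as np

from mcpalm.mobility import distribution_overlap, fit_logd_mixture
from mcpalm.pipeline import run_pipeline_frames
from mcpalm.simulate import SimulationConfig, ground_truth_compare, simulate_experiment

exp = simulate_experiment(SimulationConfig(seed=1))
res = run_pipeline_frames(exp.sm_locs, exp.cluster_locs, exp.bead_pairs)

d = res.diffusion
valid = d[d["valid"]]
mix = fit_logd_mixture(valid["D_um2_s"], seed=0)
print(f"traces: {len(d)} ({len(valid)} with positive fitted D)")
print(f"mixture components (BIC-selected): {mix.n_components}")
for w, m, s in zip(mix.weights, mix.means_log10, mix.sds_log10):
    print(f"  weight {w:.2f}: D = {10**m:.4f} um^2/s (log10 sd {s:.2f})")

bound = valid.loc[valid["label"] == "bound", "D_um2_s"]
unbound = valid.loc[valid["label"] == "unbound", "D_um2_s"]
ov = distribution_overlap(bound, unbound)
sc = ground_truth_compare(res.traces, res.classes, exp.truth, 20.0)
print(f"\nbound-vs-unbound mobility overlap: {100 * ov:.1f}%")
print(f"correlative classification accuracy: {100 * sc.accuracy:.1f}%")
print(f"best single D-threshold accuracy:    {100 * sc.best_threshold_accuracy:.1f}%")
print(
    "\nThe apparent-D distributions overlap far too much for any threshold, "
    "but assigning traces to the moving locus footprint classifies them "
    "almost perfectly."
)
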