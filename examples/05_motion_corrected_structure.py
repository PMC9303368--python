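"""Recover time-averaged locus structure from a moving locus.

Transported loci smear their bound-probe localizations along the trajectory.
Subtracting the interpolated locus path collapses them back onto the true
binding-site distribution; the radius of gyration quantifies the recovery.
"""

import numpy as np

from mcpalm.pipeline import run_pipeline_frames
from mcpalm.simulate import SimulationConfig, rg_recovery, simulate_experiment
from mcpalm.structure import render

cfg = SimulationConfig(
    seed=5, transport_fraction=1.0, transport_speed_um_s=0.015,
    n_bound=240, n_unbound=100,
)
exp = simulate_experiment(cfg)
res = run_pipeline_frames(exp.sm_locs, exp.cluster_locs, exp.bead_pairs)

table = rg_recovery(res.corrected, res.sm_registered, res.tracks, exp.truth, min_points=20)
table = table[table["displacement_um"] > 1.0]
cols = ["cluster_id", "n", "displacement_um", "rg_true_nm", "rg_corrected_nm",
        "rg_uncorrected_nm"]
print(table[cols].round(1).to_string(index=False))
ratio = table["rg_corrected_nm"] / table["rg_true_nm"]
infl = table["rg_uncorrected_nm"] / table["rg_true_nm"]
print(f"\nmedian corrected/true Rg:   {ratio.median():.2f}")
print(f"median uncorrected/true Rg: {infl.median():.2f}")

# a super-resolution rendering of the largest corrected locus
cc = max((c for c in res.corrected if c.n_localizations >= 20),
         key=lambda c: c.n_localizations)
img, _ = render(cc.points, cc.locs["precision"].to_numpy(), pixel_nm=10.0)
print(f"\nrendered locus {cc.cluster_id}: {img.shape[1]}x{img.shape[0]} px at 10 nm/px, "
      f"integrated intensity {img.sum():.1f} (= localization count)")
print(
    "\nMotion correction recovers the binding-site spread to within a few "
    "percent while raw localizations overestimate it several-fold."
)
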