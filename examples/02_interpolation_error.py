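"""How well does linear interpolation track a locus between anchor frames?

In the interleaved acquisition the conventional channel only sees each locus
every 10th frame; positions in between are linearly interpolated. This
calibration simulates telomere-like Brownian tracks localized in *every*
frame, then compares interpolated and observed positions at the skipped
frames.
"""

from mcpalm.simulate import simulate_full_rate_tracks
from mcpalm.tracking import interpolation_error_experiment

tracks = simulate_full_rate_tracks(
    n_tracks=120, n_frames=4000,       # 200 s at 20 Hz
    d_median=0.002, d_sigma_log10=0.5,  # log-normal locus mobility (um^2/s)
    noise_nm=30.0,                      # per-axis cluster localization noise
    seed=11,
)
res = interpolation_error_experiment(tracks, cycle_length=10, max_gap=20)

print(f"tracks used: {res.n_tracks}, error samples: {len(res.errors_nm)}")
print(f"median interpolation error: {res.median_nm:.1f} nm")
print("\nmean error vs anchor spacing (frames):")
print(res.as_frame().round(1).to_string(index=False))
print(
    "\nThe median error (~1/10 of a locus radius) dominates the resolution "
    "of motion-corrected images; the mean grows monotonically as anchors "
    "are spaced further apart."
)
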