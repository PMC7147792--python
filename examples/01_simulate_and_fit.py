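"""Simulate the vial phantom and recover T1 by pixel-wise fitting.

Builds the three reference vials (native myocardium-like 1078 ms,
post-contrast myocardium-like 559 ms, native blood-like 1507 ms), simulates
a 9-image saturation-recovery acquisition at 60 bpm with SNR 40, fits every
foreground voxel with the three-parameter model and reports the eroded-ROI
mean (accuracy) and SD (precision surrogate) per vial.
"""

import sashamap as sm

VIALS = (1078.0, 559.0, 1507.0)

phantom = sm.make_vial_phantom((64, 64, 6), VIALS, vial_radius_vox=9.0)
schedule = sm.generate_schedule(9, hr_bpm=60)
print(f"saturation times (ms): {[round(t) for t in schedule.finite_ts]} + full recovery")

sigma = sm.sigma_for_snr(phantom, 40.0)
stack = sm.simulate_stack(phantom, schedule, noise_sigma=sigma, seed=1)
t1map = sm.fit_volume(stack, mask=phantom.labels > 0)

for label, true_t1 in zip((1, 2, 3), VIALS):
    roi = sm.eroded_mask(phantom.region_mask(label), erode_vox=2)
    stats = sm.roi_stats(t1map, roi, label=label)
    err = 100 * (stats.mean_t1 - true_t1) / true_t1
    print(
        f"vial {label}: true T1 {true_t1:6.0f} ms -> fitted {stats.mean_t1:7.1f} "
        f"+/- {stats.sd_t1:5.1f} ms  (error {err:+.2f}%, {stats.n_voxels} voxels)"
    )
print("ROI mean tracks the true T1 within a few per mil; the SD is the")
print("voxel-wise precision that denoising (example 02) recovers.")
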