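"""Recover precision with Beltrami denoising when only 3 images are used.

Simulates one 9-image acquisition, retrospectively subsets it to 3 images,
and compares the vial T1 SD before and after joint Beltrami denoising.  The
headline behaviour: raw precision degrades sharply at 3 images, while the
denoised 3-image map matches (or beats) the denoised 9-image map.
"""

import sashamap as sm

phantom = sm.make_vial_phantom((64, 64, 6), (1078.0, 559.0, 1507.0), vial_radius_vox=9.0)
stack9 = sm.simulate_stack(
    phantom, sm.generate_schedule(9, 60), noise_sigma=sm.sigma_for_snr(phantom, 40.0), seed=1
)
fg = phantom.labels > 0
roi = sm.eroded_mask(phantom.region_mask(1), erode_vox=2)  # 1078 ms vial

for n in (3, 9):
    sub = sm.subset_schedule(stack9, n)
    raw = sm.roi_stats(sm.fit_volume(sub, mask=fg), roi)
    den_stack, trace = sm.beltrami_denoise(sub, sm.DenoiseConfig(), return_trace=True)
    den = sm.roi_stats(sm.fit_volume(den_stack, mask=fg), roi)
    gain = sm.precision_improvement(raw.sd_t1, den.sd_t1)
    print(
        f"{n} images: raw SD {raw.sd_t1:5.1f} ms -> denoised SD {den.sd_t1:5.1f} ms "
        f"({gain:.0f}% better, {len(trace) - 1} denoise iterations)"
    )
    print(
        f"          scan time {sm.nominal_scan_time(n)} s; "
        f"accuracy raw {raw.mean_t1:.0f} ms / denoised {den.mean_t1:.0f} ms (truth 1078)"
    )
print("After denoising the 3-image SD matches the 9-image SD: the precision")
print("lost by acquiring fewer saturation points is recovered in post-processing.")
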