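"""Short-axis cardiac phantom: AHA 17-segment summary and line profiles.

Simulates a myocardial ring (1078 ms) around a blood pool (1507 ms), maps T1
from 5 images before and after denoising, summarizes the map on the AHA
16+1-segment model and compares an intensity profile across blood and
myocardium, plus the Bland-Altman agreement of the two maps.
"""

import numpy as np

import sashamap as sm

phantom = sm.make_cardiac_phantom((64, 64, 12), myo_t1=1078.0, blood_t1=1507.0,
                                  ring_radii=(9.0, 15.0))
stack = sm.simulate_stack(
    phantom, sm.generate_schedule(5, 60), noise_sigma=sm.sigma_for_snr(phantom, 40.0), seed=2
)
fg = phantom.labels > 0
raw_map = sm.fit_volume(stack, mask=fg)
den_map = sm.fit_volume(sm.beltrami_denoise(stack), mask=fg)

center = ((64 - 1) / 2.0, (64 - 1) / 2.0)
bands = ((0, 4), (4, 8), (8, 12))
for name, t1map in (("raw", raw_map), ("denoised", den_map)):
    aha = sm.aha_summary(
        t1map, lv_center=center, rv_insertion_angle=0.0, slice_bands=bands,
        myo_mask=phantom.region_mask(1), blood_mask=phantom.region_mask(2),
    )
    myo = aha.table[aha.table.segment <= 16]
    blood = aha.table[aha.table.segment == 17].iloc[0]
    print(
        f"{name:>8}: myocardial segments mean {myo.mean_t1.mean():7.1f} ms, "
        f"per-segment SD {myo.sd_t1.mean():5.1f} ms; blood pool {blood.mean_t1:7.1f} ms"
    )

prof_raw = sm.line_profile(raw_map.t1_volume, (31, 16, 6), (31, 47, 6), 32)
prof_den = sm.line_profile(den_map.t1_volume, (31, 16, 6), (31, 47, 6), 32)
print("profile roughness (mean |step|) across blood+myocardium:",
      f"raw {np.nanmean(np.abs(np.diff(prof_raw))):.1f} ms,",
      f"denoised {np.nanmean(np.abs(np.diff(prof_den))):.1f} ms")

seg_raw = sm.aha_summary(raw_map, center, 0.0, bands,
                         phantom.region_mask(1), phantom.region_mask(2)).table
seg_den = sm.aha_summary(den_map, center, 0.0, bands,
                         phantom.region_mask(1), phantom.region_mask(2)).table
ba = sm.bland_altman(seg_raw.mean_t1[:16], seg_den.mean_t1[:16])
print(f"Bland-Altman raw vs denoised segment means: bias {ba.bias:+.1f} ms, "
      f"limits [{ba.loa_low:+.1f}, {ba.loa_high:+.1f}] ms")
print("Denoising smooths the profile and tightens per-segment SD without")
print("biasing the segment means (bias within a few ms of zero).")
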