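# sashamap

Accelerated 3D saturation-recovery (SASHA) myocardial T1 mapping on
synthetic data: phantom simulation, joint Beltrami denoising of the
T1-weighted image stack, pixel-wise three-parameter fitting, and
accuracy/precision evaluation.

## The problem

Saturation-recovery T1 mapping samples the longitudinal recovery curve with
several T1-weighted images at increasing saturation delays (TS), plus one
unprepared image measuring the fully recovered magnetization. Each extra
saturation point lengthens the scan (a nine-image 3D acquisition takes
minutes of free breathing), but removing points degrades the *precision* of
the fitted T1 map — the voxel-to-voxel scatter — even though the *accuracy*
(the ROI mean) barely moves. `sashamap` implements and quantifies the
remedy: denoise the T1-weighted images jointly across space and the
recovery dimension *before* fitting, so that a 3-image acquisition yields
the precision of a 9-image one.

The package is aimed at quantitative-MRI methods work: it generates
ground-truth digital phantoms (a standardized multi-vial T1 phantom and a
short-axis cardiac geometry), simulates magnitude acquisitions with
controlled SNR, and measures exactly how accuracy and precision respond to
the number of saturation points, before and after denoising.

## The model

Signal at saturation delay TS for a voxel with relaxation time T1,
equilibrium signal A and saturation efficiency B:

    S(TS) = A · (1 − B · e^(−TS/T1)),        S(∞) = A

Pixel-wise mapping solves the bounded nonlinear least-squares problem for
(A, B, T1); the unprepared image enters analytically as the TS = ∞ sample.
Saturation delays are spaced equally between TS_min = 54 ms and
TS_max = RR − 260 ms (740 ms at 60 bpm).

Denoising minimizes one joint Beltrami energy over the stack u with data f:

    E(u) = Σ_voxels √(1 + β² Σ_c |∇u_c|²) + (λ/2) Σ_c ‖u_c − f_c‖²

All contrasts c share the manifold metric, so edges supported by every
saturation time are preserved in every image while noise is removed; the
√(·) area element interpolates between isotropic smoothing (flat regions)
and total variation (edges) without staircasing. Gradients are scaled by
the physical voxel spacing (default 1.4 × 1.4 × 8 mm).

## Worked example

`examples/02_denoise_precision.py` simulates one 9-image vial acquisition
at SNR 40, retrospectively subsets it to 3 images, and maps T1 before and
after denoising:

```
3 images: raw SD 102.5 ms -> denoised SD  25.9 ms (75% better, 12 denoise iterations)
          scan time 85 s; accuracy raw 1081 ms / denoised 1074 ms (truth 1078)
9 images: raw SD  75.9 ms -> denoised SD  29.1 ms (62% better, 13 denoise iterations)
          scan time 254 s; accuracy raw 1080 ms / denoised 1077 ms (truth 1078)
```

Reading the numbers: the ROI mean (accuracy) stays within a few ms of the
1078 ms ground truth in all four maps, so dropping saturation points does
not bias T1. The raw ROI SD (the precision surrogate) inflates from 76 to
103 ms when only 3 of the 9 images are fitted — but after denoising the
3-image map (25.9 ms) is as precise as the denoised 9-image map (29.1 ms),
at a third of the nominal scan time (85 s vs 254 s).

The other examples cover simulation + fitting (`01`), the full
accuracy/precision vs image-count table (`03`), and the cardiac phantom
with AHA 17-segment summaries, line profiles and Bland-Altman agreement
(`04`). A thin CLI mirrors the pipeline stages:

```sh
sashamap simulate --out run/ --n-images 9 --snr 40 --seed 1
sashamap denoise  --in run/stack.nii.gz --schedule run/schedule.json --out run/den.nii.gz
sashamap fit      --in run/den.nii.gz --schedule run/den.schedule.json --out run/t1map.nii.gz
sashamap evaluate --t1map run/t1map.nii.gz --labels run/truth/labels.nii.gz \
                  --truth run/truth/regions.csv --out run/report/
```

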