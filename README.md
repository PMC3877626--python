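# petgtm — region-based partial volume correction for PET

PET scanners resolve activity at ~5–8 mm, so the measured uptake of any
structure comparable to that scale is biased: signal spills out of small
hot regions and in from their neighbours (the point-response effect),
and coarse voxels mix tissue types (the tissue fraction effect).
Quantitative studies — striatal tracer binding, small-lesion SUVs,
phantom QA — need this bias removed. `petgtm` implements the four
classical **region-based partial volume corrections** built on the
geometric transfer matrix, together with the digital phantoms and the
Monte-Carlo harness used to characterize them. It is aimed at
physicists and methods researchers who want a transparent, fully
scriptable reference implementation rather than a scanner console
black box.

## The model

Anatomical (CT/MR) segmentation gives N non-overlapping regions
VOI_j with assumed-homogeneous uptakes T_j. Each region's **regional
spread function** RSF_j is the image a unit-uptake region would
produce through the scanner's resolution model, so the noise-free PET
image is I(r) = Σ_j T_j·RSF_j(r). Sampling both sides with weighting
functions w_i yields the linear system

```
ω_ij T_j = t_i ,   ω_ij = ∫ RSF_i(r) w_j(r) dr ,   t_j = ∫ I(r) w_j(r) dr
```

solved directly for the corrected uptakes T. The four methods are the
cells of a 2×2 design:

| | RSF by PSF convolution | RSF by project/blur/reconstruct |
|---|---|---|
| **sample with sharp VOI masks** (w_j = VOI_j) | GTM | GTMo |
| **sample with the RSFs** (w_j = RSF_j, symmetric ω) | sGTM | sGTMo |

The sinogram-space methods (suffix “o”) push each mask through a
parallel-beam forward projection, a calibrated Gaussian sinogram blur
and filtered back-projection, so the RSFs carry the reconstruction's
actual behaviour (including negative values and streaks). The
symmetric methods sample the image with the blurred RSFs instead of
sharp masks, which makes ω a Gram matrix and improves noise
propagation and robustness to mask/PET misregistration — the package
exists to quantify exactly those claims, for sGTMo in particular.

Supporting machinery, all first-class and tested:

* **phantoms** — a six-sphere hollow-sphere tank (5–30 mm inner
  diameter, 0.6 mm cold walls, 3:1 sphere-to-background ratio, 0.6 mm
  fine grid) and a six-region procedural brain (putamen 4.5, caudate
  4.0, skin/muscle 1.0, grey 2.5, white 2.0, background 0), plus
  tissue-fraction downsampling, stationary Gaussian noise and rigid
  mask shifts;
* **projector** — sparse, exactly-adjoint Joseph projector,
  Fourier-domain Gaussian sinogram blur, Ram-Lak/Hann FBP, and PSF
  calibration by root-finding on a simulated point source;
* **evaluation** — recovery coefficients (RC = measured/true uptake),
  noise magnification factors (NMF = CV(T)/CV(t)) and misregistration
  sweeps over 100-realization Monte-Carlo ensembles.

## Worked example

Simulate a noisy brain acquisition and correct it with sGTMo:

```python
from petgtm import (
    DEFAULT_PSF_FWHM, PVCConfig, RegionPVC, add_noise, build_brain_study,
    calibrate_blur, simulate_acquisition,
)

study = build_brain_study()          # six-region labelled head + ideal image
blur = calibrate_blur(DEFAULT_PSF_FWHM,
                      grid_shape=study.pet_shape, voxel_size=study.pet_voxel)

pet = simulate_acquisition(study.ideal_pet, blur)          # project/blur/FBP
pet = add_noise(pet, 0.25, study.noise_reference, rng_seed=42)

model = RegionPVC(pet, masks=study.masks, region_names=study.region_names,
                  method="sGTMo",
                  config=PVCConfig(psf_fwhm=DEFAULT_PSF_FWHM, blur=blur))
res = model.fit(sigma_noise=0.25 * study.noise_reference)
print(res.summary())
```

```
Region-based PVC (sGTMo, sinogram-space RSFs)
regions: 6   condition number: 915

region                   sampled t   corrected T       se(T)
background                   88217    0.00099807      0.0014
putamen                      24625        4.5125      0.0281
caudate                      12582         3.901      0.0414
skin_muscle             2.6257e+05       0.99741     0.00538
grey_matter             5.2113e+05        2.4985     0.00484
white_matter            8.4648e+05        1.9976      0.0029
```

The sampled values t are the raw (partial-volume-biased) regional
integrals; the corrected uptakes T land on the true relative uptakes
(4.5, 4.0, 1.0, 2.5, 2.0, 0) to well within the analytic standard
errors, despite 25% voxel noise. The condition number reports how
noise-sensitive the inversion is for this region set.

The same machinery is available from the shell:

```sh
petgtm calibrate-psf --fwhm 7.23 7.14 6.65
petgtm correct --method sgtmo --pet pet.nii --labels labels.nii --out result.json
petgtm evaluate --phantom spheres --nreal 50 --seed 1 --out report/
```

(`petgtm evaluate` writes `rc.csv`, `nmf.csv`, a config snapshot and
summary plots.)

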