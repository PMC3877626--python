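# Methods

This note records the model assumptions, the numerical design of the
acquisition simulator, the construction of the phantoms and the
evaluation harness, and the limitations a user should know before
trusting numbers from this package.

## 1. The transfer-matrix model and its assumptions

All four corrections share one generative model: the anatomy is
partitioned into N regions of *homogeneous* uptake T_j, and the
noise-free PET image is the superposition I = Σ_j T_j RSF_j of the
regional spread functions. Sampling I with weighting functions w_i
produces ω T = t with ω_ij = ∫ RSF_i w_j and t_j = ∫ I w_j, solved by
dense LU (`numpy.linalg.solve`); the matrix is never inverted
explicitly. The integrals are voxel sums scaled by the voxel volume;
the scale cancels in the solve but keeps ω physically interpretable
(mm³ of spill).

Assumptions this buys:

* **homogeneity** — a region with internal uptake structure biases
  its own and its neighbours' estimates;
* **correct segmentation and registration** — the masks are taken as
  truth; misregistration is studied explicitly (below);
* **known resolution model** — either a global Gaussian PSF (GTM,
  sGTM) or the project/blur/reconstruct chain (GTMo, sGTMo). When the
  image was actually formed by the same linear operator used for the
  RSFs, the solve recovers T *exactly* (to solver precision) on
  noise-free data: this algebraic identity is the primary oracle of
  the test suite.

Exactness also requires that every activity-generating structure is
spanned by the region set. Zero-uptake surroundings (air) need no
region; a warm structure outside the modelled set does.

The symmetric variants (w_j = RSF_j) make ω a Gram matrix — symmetric,
and positive semidefinite for image-space RSFs. Algebraically, sGTM
sampling turns the solve into the ordinary least-squares estimator of
T under the superposition model, which is why its noise propagation is
the best achievable among unbiased linear estimators (see §6).

## 2. Acquisition simulator

The scanner is idealized as a slice-parallel parallel-beam system:
2D Radon transform per transaxial slice, Gaussian blur of the
projections, 2D filtered back-projection per slice. The blur is
applied radially by multiplying the projection's Fourier transform
with a Gaussian (by the central-slice theorem this equals an isotropic
in-plane image blur) and axially by the same exact frequency-response
Gaussian along the slice direction, so blurs compose exactly and
per-angle counts are conserved to numerical precision.

Numerical choices, each load-bearing:

* **Projector.** Joseph-style bilinear sampling along rays, with two
  refinements: every detector bin is split into 3 sub-rays whose
  contributions are averaged (finite bin width; suppresses a ±4%
  center-of-rotation checkerboard that voxel-size stepping produces),
  and the ray step is one third of the radial spacing. Per angle the
  operator is assembled once as a sparse matrix and cached, so the
  backprojector is its *exact transpose*: ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to
  machine precision, and per-angle count conservation is exact by
  construction of the deposit weights.
* **Geometry defaults.** 192 angles uniform in [0, π), radial spacing
  equal to the in-plane voxel size, radial extent 1.1× the image
  diagonal.
* **FBP filter.** The ramp is built from the band-limited
  spatial-domain kernel (h[0] = 1/4d², h[odd] = −1/(πkd)²) and then
  apodized; sampling |f| directly in the frequency domain leaves a
  ~1% DC bias that a partition-of-unity method cannot afford. Default
  window: Hann at the Nyquist cutoff; ramp and Shepp-Logan are
  available. The same filter is always used for the RSFs and the
  simulated PET image — both sides of ωT = t must see the same system.
* **Field-of-view edges.** `simulate_acquisition` replicate-pads the
  image in-plane by 16 voxels before projection and crops after
  reconstruction, mirroring the replicate-edge convolution used for
  image-space RSFs. This makes the reconstruction of the constant
  image flat to ~0.15% over the whole grid, which is what lets the
  summed sinogram-space RSFs stay within 0.5% of unity at *every*
  voxel — the validity check of the sinogram-space methods.
* **PSF calibration.** σ_radial is root-found (Brent) so that the
  Gaussian-fitted in-plane FWHM of a reconstructed point source
  matches the mean of the x/y targets; σ_axial likewise for z (slices
  are independent, so the axial profile is the blur kernel itself).
  The sinogram blur is in-plane isotropic — with the default targets
  (7.23, 7.14, 6.65 mm) the individual fitted FWHMs land within 0.7%
  of each target. Targets below the intrinsic resolution of the
  discrete projector (≈4.8 mm at 2 mm voxels with the Hann window) are
  rejected with the measured floor. FWHM = 2√(2 ln 2)·σ throughout.

Sub-voxel blur sigmas are Nyquist-limited: the discrete Gaussian is
truncated in frequency, so identities like the semigroup property hold
to 1e-6 only for sigmas comfortably above the sampling scale.

## 3. Phantoms

**Sphere tank.** Six hollow spheres (inner diameters 5, 8, 13, 17, 22,
30 mm; 0.6 mm zero-uptake walls; interior:background = 3:1) in a warm
tank that fills a 64×64×48 grid of 2×2×3.15 mm PET voxels, built
analytically on a 0.6 mm fine grid by voxel-center membership. The
spheres sit three per axial plane on a 26 mm ring, two planes 74 mm
apart, so that each sphere's local background cylinder (radius and
half-height = outer radius + 20 mm) fits the grid and spheres never
intrude into each other's cylinders by more than a negligible sliver.
Each sphere is corrected with its own 3×3 system {interior, wall,
tank background}, with all integrals weighted by the local cylinder;
the background RSF is that of the *full* tank background, which is
what keeps the exact-recovery identity intact across the cylinder
boundary.

**Brain.** A procedural surrogate head of nested ellipsoids:
skin/skeletal-muscle shell, grey-matter shell, white-matter core, and
paired caudate and putamen ellipsoids (left+right merged into one VOI
per structure, matching the five-uptake assignment). Region volumes
are of human order (putamen ≈ 3.8 ml/side, caudate ≈ 2.2 ml/side,
grey ≈ 257 ml, white ≈ 407 ml). Relative uptakes 4.5 (putamen), 4.0
(caudate), 1.0 (skin/muscle), 2.5 (grey), 2.0 (white), 0 (background);
fine grid 1.1×1.1×1.4 mm; one global 6×6 system. Any user-supplied
labelled atlas can replace the surrogate.

**Tissue fractions.** Fine binary masks are resampled to the PET grid
by plain trilinear interpolation at PET voxel centers — the convention
of the region-based PVC literature. An `antialias=True` option
box-prefilters first, which yields true within-voxel volume fractions;
it is *off* by default because the extra smoothing makes the spread
functions of a sphere interior and its sub-voxel wall substantially
more collinear and thereby triples the noise amplification of the
correction for the smallest structures. Both routes preserve the
partition of unity exactly (linear, constant-preserving resampling of
an exhaustive label set).

**Noise.** Stationary, uncorrelated Gaussian noise added to the
reconstructed image, std = 25% of the reference mean — the tank
background mean (≈1) for the spheres, the mean over nonzero-uptake
head tissue (≈1.9) for the brain, where no single reference
compartment exists. Post-reconstruction white noise is a deliberate
simplification: FBP noise is in reality spatially correlated; see §7.
One master seed spawns independent `SeedSequence` streams per
realization and per image branch, so every ensemble is exactly
reproducible.

## 4. Evaluation harness

Accuracy and precision are summarized by the recovery coefficient
RC = measured/true regional activity (corrected: T_i/truth; without
PVC: tissue-fraction-weighted image mean / truth), tabulated as
mean ± std over realizations. Zero-uptake regions (sphere walls, brain
background) have undefined RC; the tables carry their absolute
corrected uptake instead. Noise propagation is the noise magnification
factor NMF = CV(T_i)/CV(t_i), each method judged against its own raw
sample (mask-weighted for GTM/GTMo, RSF-weighted for sGTM/sGTMo).

Misregistration is applied one axis at a time, up to 10 mm. Two modes:

* `mode="image"` (default): the PET image is shifted against the fixed
  mask frame by whole PET voxels. Physically the same relative
  displacement, but the RSFs and ω are bit-identical across shifts —
  which turns the statement "registration errors affect only the
  sampled t values, not the weighting matrix" into an exact property —
  and no RSF recomputation is needed.
* `mode="labels"`: the fine-grid labels are shifted (nearest fine
  voxel), re-downsampled, and the RSFs recomputed per shift — the
  literal acquisition-side procedure. The two modes agree to a few
  percent, differing by shift granularity (0.6 vs 2 mm rounding).

RC-vs-shift curves are normalized to the zero-shift RC of the same
method and region, so every curve starts at exactly 1.

Default problem sizes — 64×64×48 PET grid, 192 angles, 100
realizations — run the full study in a few minutes on one core; all
are parameters.

## 5. Design choices that were genuinely open

* **Fractional vs binarized sampling masks.** Eq.-style sampling with
  tissue fractions is the default; a `binarize_masks` option exists.
  Binarization is unusable for sub-voxel structures (the 0.6 mm walls
  have no voxel above 0.5 fraction — a singular system).
* **Left/right striatal structures** are merged into one VOI per
  structure (consistent with assigning five uptakes to five VOIs);
  a user atlas with split sides works unchanged.
* **Per-sphere local systems** rather than one 13×13 joint system:
  matches the physical-phantom analysis practice and keeps each
  correction local; the global background region is shared.
* **Condition-number warning** above 1e6 (configurable), with an
  optional ridge term that is off by default — the classical methods
  use the plain inverse.

## 6. The 5 mm sphere: a statistical wall

With a 7.2 mm PSF, a 5 mm sphere and its 0.6 mm wall produce almost
parallel spread functions (cos similarity 0.96); separating their
uptakes is intrinsically ill-posed. The best linear unbiased estimator
of the 5 mm interior uptake under 25% voxel noise — which the sGTM
solve *is* — has std(RC) ≈ 0.53; the mask-sampled GTM estimator is ≈3×
worse. Consequently the Monte-Carlo mean RC of this sphere carries an
SE of 0.05–0.24 even at 100 realizations, and a blanket "mean RC
within 5%" cannot hold reliably there for any implementation.
Everything from 8 mm up sits within ~1–2%. The same collinearity
explains the large NMFs (tens) at 5 mm, and one subtlety: at 5 mm the
*NMF* of sGTMo exceeds that of GTMo even though its absolute noise is
3× lower, because the symmetric method's own raw sample t (the NMF
denominator) is far less noisy than the mask-weighted sample. From
8 mm upward the symmetric methods win on NMF and on std(RC) alike.

## 7. What the synthetic studies do not show

* **Noise spectrum.** White post-reconstruction noise underweights the
  long-range correlations of projection-domain (Poisson) noise;
  absolute NMF values would shift with correlated noise, though the
  method orderings are driven by the sampling functions.
* **Physics.** No attenuation, scatter, randoms, positron range,
  detector parallax or depth-of-interaction: the resolution model is a
  globally shift-invariant Gaussian, so the sinogram-space methods'
  distinctive ability to carry spatially *varying* resolution is
  exercised structurally (negative RSF values, streaks, reconstruction
  coupling) but not quantitatively.
* **Geometry.** Slice-parallel parallel-beam FBP stands in for a
  cylindrical-scanner 3D reprojection algorithm; oblique line-of-
  response effects are absent.
* **Anatomy.** The surrogate head is schematic; conclusions transfer
  through region size and contrast, not shape fidelity.
* **Homogeneity.** Real tissue is not piecewise constant; none of the
  phantoms probe model misspecification from intra-regional structure.
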