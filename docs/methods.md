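# Methods

`retnav` re-creates, in software, the computational chain of a multimodal
murine retinal imaging platform that combines optical coherence tomography
(OCT), two-channel scanning laser ophthalmoscopy (SLO), and a navigated
532 nm photocoagulation laser.  Because every stage is exercised against a
synthetic phantom with exact ground truth, the package runs and validates
end to end with no instrument and no external data.  This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic benchmarks do and do not establish.

## Coordinate and data conventions

OCT volumes carry axes (repeat, slow y, fast x, depth z) with depth
increasing away from the vitreous: the inner retina sits at low z, the
retinal pigment epithelium (RPE) at high z.  En face coordinates are
micrometres from the volume corner, pixel centres at (index + 0.5) x pitch.
SLO stacks are (time, channel, row, col) with channel 0 the red (tdTomato)
and channel 1 the green detection band.  Files are multi-page float32 TIFF
with JSON sidecars; nothing is inferred from file contents alone.

## Phantom (synthetic retina)

The phantom is generative, seeded, and bit-reproducible.  Its components:

* **Layered axial profile.** Six Gaussian reflectivity bands (NFL, IPL,
  INL, OPL, ONL, RPE) at fixed depths (160-400 um) on a dark background;
  the OPL (0.75) and RPE (1.0) are the brightest outer-retina bands, which
  is what the surface detector assumes.  A parabolic axial bow (default
  peak 60 um across the field) models retinal curvature; vessels are
  straight tubes that attenuate everything below them (shadowing), the
  dominant real-world failure mode for per-A-scan peak detection.
* **Speckle and noise.** Repeats differ only by independent multiplicative
  Gaussian speckle (contrast 0.25) plus an additive floor (0.02), clipped
  at zero.  Per-voxel std across repeats is therefore
  sqrt((0.25 I)^2 + 0.02^2), which the tests check directly.  True OCT
  speckle is neither Gaussian nor spatially white; this choice makes the
  repeat-averaging oracle exact while preserving the contrast-to-noise
  regime of averaged B-scans.
* **Lesion dose response.**  The instrument literature for this platform
  reports only qualitative lesion behaviour: lesions anchor at the RPE
  (melanin absorption), scattering contrast accumulates pulse by pulse, and
  damage propagates inward at higher dose.  The phantom encodes this as a
  multiplicative gain

      g = 1 + dmax (1 - exp(-E / E0)) G_lat(x, y) A(z; E),

  with total delivered energy E = power x duration x repeats (mJ)
  accumulated across pulses at a site before the response is evaluated.
  G_lat is a Gaussian footprint (sigma 25 um, half the default 50 um
  retinal spot); A is a box anchored at the RPE extending inward by
  5 um/mJ, clipped at the OPL.  Defaults: E0 = 1.2 mJ (one 6 mW x 200 ms
  pulse reaches 63% of saturating gain), dmax = 3.  The ground-truth lesion
  mask is the region with g > 1.2.  Consequences the tests rely on: lesion
  volume is monotone in E; the axial extent has the closed form
  min(5 um/mJ x E, RPE-OPL distance); a single low-severity pulse stays
  confined below the OPL, so contrast appears on the outer but not the
  inner en face projection.
* **Photoconversion.**  The red-to-green spectral shift of tdTomato is
  modelled as a converted fraction phi = 1 - exp(-kappa E) with kappa =
  0.8 / mJ under the same lateral footprint: one pulse converts ~62%, four
  pulses ~98% ("almost complete" at high severity).  Red = tdTomato x
  (1 - phi); green = baseline + tdTomato x phi x leak gain.  A single
  recovery fraction models the partial day-7 return of red signal; no
  kinetics are claimed.
* **Respiratory motion.**  A Poisson number of events (rate 1.5 Hz, the
  middle of the observed 1-2 Hz) displaces distinct frames rigidly by
  40 um laterally (< 50 um as observed).  Event durations (30-100 ms) are
  shorter than the 128 ms frame interval, so whole-frame displacement
  rather than intra-frame shear is a reasonable first-order model; shear
  and the axial component (which in en face SLO would appear as defocus)
  are not emulated.
* **Grid target.**  Calibration data are an n x n spot grid (default 7 x 7,
  100 um spacing, optionally rotated) rendered in both modalities; the
  observed positions are the commanded voltages passed through an arbitrary
  polynomial distortion, and the SLO rendering through a configurable
  inter-modality warp, both recorded as ground truth.

Defaults mirror the platform's acquisition geometry (500 x 500 positions,
5 repeats, 200 SLO frames of 1024 x 1024 at 7.8 Hz).  Tests and benchmarks
explicitly pass a desk-scale geometry (64 x 64 x 128 voxels at 8/8/4 um,
256 x 256 SLO at 2 um) so the full suite runs in minutes; the dose, noise
and motion parameters are untouched by this rescaling.

## Calibration and co-registration

Both maps are full tensor-product bivariate polynomials fitted by least
squares on coordinates affinely scaled to [-1, 1]^2 for conditioning, with
coefficients reported in the natural monomial basis (the basis change is
exact).  Degree defaults to 3 — enough for smooth scan-field distortion,
few enough coefficients (16 per axis) for a ~50-point grid.
Underdetermined or rank-deficient designs raise rather than regularise.

Inversion (voltage targeting) is damped Newton with the analytic Jacobian,
seeded from the best point of a 50 x 50 forward-sampled domain grid;
convergence demands a residual <= 0.1 um within 100 iterations, and
solutions landing far outside the fitted voltage domain are rejected as
out-of-image targets.

Landmark detection smooths with a Gaussian (sigma = spacing/10), takes
local maxima at least half a spacing apart and a configurable prominence
above background, then refines each to an intensity-weighted centroid in a
one-spacing window after local background subtraction and soft
thresholding at 20% of the window peak (without the threshold, background
noise biases centroids by ~0.3 px at SNR 20; with it, errors are < 0.2 px).
Matching is mutual-nearest-neighbour after a similarity Procrustes
pre-alignment on the four extreme corners.  The unwarp is stored SLO pixel
-> OCT micrometre (OCT en face is the canonical frame because lesion plans
live there); resampling is inverse-mapping bilinear interpolation with a
NaN sentinel outside the mapped domain and a reported coverage fraction.

## OCT processing

Repeats are averaged arithmetically (a pluggable denoiser hook exists; no
further denoising is claimed).  The RPE is the per-A-scan argmax after a
3-voxel axial median filter; because vessel shadows can dim the RPE below
inner layers on isolated A-scans, outliers are re-snapped to the strongest
peak within 30 um of the laterally median-smoothed surface before the final
2D median smooth (default window 60 um).  The OPL is the strongest local
maximum 40-200 um inner to the RPE.  A volume where more than 5% of A-scans
lack a peak 3x above the median intensity is rejected as featureless.
Flattening shifts each A-scan by an integer voxel count so the reference
surface sits at its median depth, zero-fills, and returns the shift map and
a validity mask; it is exactly invertible on surviving voxels.  En face
projection reduces the half-open slab [top, bottom) — half-open so that
adjacent slabs partition the volume — with mean (default), max, or sum;
whether the original system averaged or summed over depth is not knowable
from the imagery, so the reducer is exposed.

## SLO processing

Motion QC scores each frame by normalized cross-correlation against the
stack median frame after alignment, and rejects on score <
median - 3 MAD or displacement > 10 px; both gates are exposed.  The
displacement gate does the heavy lifting for respiratory events (which are
rigid and large); the robust score gate catches frames the reference
misrepresents.  Registration is translation-only (observed motion is small
and lateral; no rotation hook is claimed) by cross-correlation on
mean-subtracted frames — the DC term otherwise biases the peak toward zero
lag — with upsampled-DFT sub-pixel refinement, the red-channel shift
applied to both channels, and NaN-aware averaging at borders.

The photoconversion index is p = G' / (G' + R), with G' the green signal
above the pre-lesion baseline and R the post-lesion red signal; the bounded
form stays stable where conversion is complete (R -> 0), unlike the raw
ratio G'/R.  Pixels with total signal below a noise floor are NaN.  Lesion
localization thresholds p > 0.5 and takes connected-component centroids
above a minimum area.

## Lesion planning

"50% spot-size overlap" is interpreted as centre pitch = 0.5 x spot
diameter (adjacent discs overlap by half a diameter); the measured overlap
(diameter - pitch)/diameter on a default plan is exactly 50%.  The raster
is row-major (serpentine optional), anchored at the treatment-mask bounding
box offset by one spot radius, so plans translate with the mask.  The keep
rule is conservative: every pixel whose centre lies within the spot radius
must exist and be treatment, and none may be exclusion; an allow-partial
flag relaxes the inside requirement but never the exclusion rule.  The rule
is defined purely on pixel centres so it can be checked against brute-force
enumeration exactly.  Schedules place repeats at onset gaps of
duration + interval with a 1 ms inter-site settle, and voltages come from
Newton inversion of the calibration; energy bookkeeping
(sum of power x duration = sites x repeats x power x duration) is exact.

## Lesion segmentation

The segmenter is a compact 2D U-Net operating on flattened B-scans: double
3x3 conv + ReLU blocks, 2x2 max pooling, nearest-neighbour upsampling with
skip concatenation, 1x1 output head, one logit per pixel.  It is
implemented directly in NumPy (sliding-window einsum convolutions, manual
backpropagation, Adam) and is fully seeded: two runs with one seed produce
identical logs and metrics.  The reference configuration is depth 4 /
16 base channels / 128 x 128 patches, up to 50 epochs; the benchmark preset
used throughout the tests is depth 3 / 8 base channels / 64 x 64 B-scans /
20 epochs, batch 8, Adam lr 3e-3, cross-entropy plus a 0.5-weight soft-Dice
term (the Dice term counters the ~2% foreground imbalance).  Inputs are
standardized per B-scan and reflect-padded to multiples of 2^depth.

Protocol utilities reproduce the platform's training design: a seeded
80/20 split (40 volumes -> exactly 32/8) and 5- or 10-fold partitions.
Training logs per-epoch loss and validation Dice and returns the
best-validation checkpoint.  Dice conventions are explicit: empty vs empty
is 1.0, empty vs non-empty 0.0.  Per-lesion metrics use 26-connectivity;
thickness is the maximum per-(y, x) axial voxel count times the axial
pitch.

**Benchmark.**  The standard benchmark is 12 flattened phantom volumes of
5 B-scans each (60 B-scan pairs), one lesion per volume placed in the
central field with dose drawn from the titration protocol used for the
platform's segmentation study: 4 x 100 ms pulses at 10-50 mW (4-20 mJ).
Volumes are cropped after flattening to a 64-voxel depth band ending one
outer layer below the RPE — the lesion response lives entirely in that band
— which halves training cost without discarding signal.  On this benchmark
the preset reaches held-out Dice ~0.9 (threshold 0.80 in the acceptance
suite) and strictly monotone segmented lesion volume across the 5-level
titration.  What this shows: the architecture, training loop, protocol
plumbing and metrics are correct, and the segmenter resolves the phantom's
dose-response ordering.  What it does not show: performance on real OCT,
where speckle statistics, annotation noise, and lesion appearance are far
richer than the phantom's.

## Numerical and degenerate-input choices

* Polynomial fits raise on n < (degree+1)^2 points or rank deficiency.
* Newton inversion errors carry the final residual; singular Jacobians
  raise rather than pseudo-invert.
* Surface maps are validated (OPL strictly above RPE everywhere); en face
  bounds must satisfy top < bottom per pixel.
* Flatten shifts are integers; fractional-voxel flattening is deliberately
  avoided to keep the operation exactly invertible.
* The motion-QC MAD gate has a 1e-12 floor so identical frames (MAD = 0)
  are not all rejected.
* Mask binarization threshold is 0.5; probability maps are always returned
  so thresholds can be revisited.

## Known limitations

* No physical optics: PSF, confocal sectioning, aberrations, and
  spectral-domain reconstruction are out of scope; the phantom emits
  reconstructed linear-intensity volumes directly.
* Lesion and photoconversion dose responses are phenomenological; constants
  are config-exposed, not fitted to data.
* Registration is translation-only; rotation and intra-frame shear are not
  modelled or corrected.
* The segmentation benchmark is synthetic; no claim is made about Dice on
  real annotated volumes.
* Longitudinal remodelling (lesion contraction, radial glial patterns) is
  not generated beyond the single photoconversion recovery fraction.
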