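# Methods

## The problem

Lymphatic vessels and aqueous veins carry optically transparent fluid
(lymph, aqueous humor), so they backscatter almost no light and appear as
dark tubes in OCT scans of ocular tissue. Segmenting them label-free from
the intensity signal requires separating "dark because transparent" from
"dark because deep": the OCT signal also decays with depth through tissue
attenuation and through the instrument's axial response. This package
implements two segmenters and the machinery to evaluate them:

1. **Conventional OCTL** (`octl.conventional`): a physics-based pipeline —
   system-response correction, per-A-scan attenuation fitting and
   compensation, constant-threshold segmentation below the detected tissue
   surface.
2. **DL-OCTL** (`octl.unet`): a U-Net trained on the conventional
   pipeline's output labels, segmenting B-scans directly.

Because the original scans are not redistributable, a synthetic phantom
generator (`octl.phantom`) provides test volumes with geometric ground
truth.

## Signal model

The renderer and the fitting stage share the single-scattering picture.
With depth `z` (physical mm below the tissue surface), attenuation
coefficient `mu` (mm^-1), and axial system response `H(z)`:

    I(z) = I0 * H(z) * exp(-2 * mu * z)

Displayed values are `10*log10(I)`; on that scale the model is a straight
line with slope `-2 * mu * (10/ln 10)` dB per mm, and the attenuation
coefficient follows from an ordinary least-squares line fit as
`mu = -slope * ln(10)/20`. The factor of 2 is the round trip. All axial
pitches are stored in optical path length; physical depth is optical depth
divided by the group refractive index (default 1.4, appropriate for ocular
tissue at 1300 nm). Two consequences used throughout: a 5.5 um axial
resolution in air is 3.9 um in tissue, and a 3.6 mm optical depth range is
2.6 mm of tissue.

`H(z)` combines the confocal collection efficiency (modelled as a
Lorentzian in depth around the focus: focus 300 um, apparent Rayleigh
range 500 um by default) and the spectral-domain sensitivity roll-off
(linear in dB, default 6 dB/mm optical). The forms are internal choices of
the generator; the pipeline never assumes them — it estimates `H(z)`
nonparametrically from a calibration scan.

## Phantom generator

`PhantomSpec` fixes the geometry (default for the pipeline: 128 x 64
A-scans, 384 depth pixels at 5.46875 um optical pitch, i.e. 3.906 um of
tissue per pixel so that a 500 um crop is exactly 128 pixels; 10 um
lateral pitch), the tissue (`mu_t` default 4 mm^-1, in the scleral range
at 1300 nm; surface level 45 dB above the noise floor, a good-quality
ex vivo scan), and the noise. Speckle is multiplicative unit-mean
exponential intensity noise (fully developed speckle; `speckle_contrast`
interpolates to noiseless), and the noise floor is additive intensity at
0 dB. Setting `noise_floor_db` very low (e.g. -120) yields the idealized
noiseless phantom used by the analytic tests.

Vessels are tubes around polylines; ground truth is geometric
(centre-to-centerline distance <= local radius, evaluated in physical
micrometres so anisotropic pitches give correctly shaped tubes), never
intensity-based. Interiors are darker by a configurable deficit (default
20 dB — strong transparency contrast). `sample_vessels` draws
lymphatic-like tubes (wandering centerline, uneven calibre) and vein-like
tubes (straight, constant calibre); the default population (5 lymphatic +
3 veins, radii 30-70 um, i.e. diameters of 60-140 um in the conjunctival
range) yields en face area densities around 40 %, matching the dense
networks such scans show. Both kinds run at an angle to the B-scan
direction: each vessel drifts laterally by up to ~1/3 of the field across
the volume. The drift matters — vessels exactly parallel to the scan axis
would put their cross-sections at identical positions in every B-scan, and
a segmenter trained on such volumes can memorize positions instead of
appearance. An optional superficial layer (thickness/deficit, default
75 um / 10 dB in the heterogeneous test phantom) emulates a
low-backscatter epithelium that violates the depth-homogeneity assumption
of the attenuation fit.

What the generator does **not** emulate: shadowing under vessels,
multiple scattering, motion, birefringence, spatially correlated speckle,
vendor-specific artifacts. Tests passing on these phantoms demonstrate
the correctness of the algorithms under the stated model, not performance
on real scans.

The raw-spectra simulator produces wavelength-sampled interferograms
(non-uniform in wavenumber) with cosine fringes `2 a cos(2 k z)` under a
Gaussian source envelope, with the spectral span chosen so that the
reconstruction axial pitch matches the spec. Reconstruction follows the
standard spectral-domain flow: background subtraction, linear resampling
onto a uniform wavenumber grid, apodization (Hann by default), inverse
FFT, `10*log10(|A|^2)` of the positive-depth half. Linear resampling has a
real frequency-dependent roll-off, so deep reflectors reconstruct a few
percent weaker than shallow ones; the linearity checks therefore compare
nearby depths.

## Conventional pipeline: numerical choices

- **Noise normalization**: the mean dB of the deepest 10 % of samples
  (assumed fully attenuated) is subtracted, putting the floor at 0 dB.
- **Surface detection**: per-B-scan Canny (sigma 2 px) on the image
  clipped from below at +3 dB — values within a few dB of the floor are
  speckle, and without clipping their gradients seed spurious edges above
  the surface. Hysteresis thresholds are 0.1/0.3 of the scan's
  gradient-magnitude range; per A-scan the shallowest edge wins; gaps are
  interpolated laterally and the map is median-filtered (15 px). A scan
  with <1 % of pixels more than 5 dB above the clipped floor is treated
  as tissue-free; a volume with no detected edges returns a zero map
  flagged unreliable.
- **System response**: laterally averaged dB profile of the calibration
  scan plus the known `2*mu_cal*z` slope, re-zeroed at its peak, trusted
  down to the last depth 3 dB above the floor and held flat beyond. A
  homogeneity guard rejects calibration scans whose lateral dB spread
  exceeds 8 dB (fully developed speckle alone gives ~5.6 dB).
- **Fit window**: from `surface + 5` px down to the last sample whose
  axially smoothed (15-px moving average) signal stays 3 dB above the
  noise floor; windows shorter than 20 px are flagged invalid. Smoothing
  is essential under speckle: isolated spikes in the noise tail would
  otherwise drag windows into pure noise and bias `mu` low. After system
  correction the noise floor is no longer 0 dB but `-H(z)` (subtracting
  `H` lifts the deep noise), and the window test uses that profile.
  Remaining bias is physical: the additive floor flattens the signal tail,
  so `mu` is underestimated by a few percent at realistic SNR (about -6 %
  at 45 dB surface SNR, mu = 2/mm).
- **Compensation** adds `2*mu*(z - surface)` in dB below the surface for
  valid A-scans; invalid ones pass through. The fit uses whole A-scans —
  vessels are not excluded — so A-scans crossing large vessels carry a
  biased `mu` and residual depth tilt. This is an inherent artifact of the
  method, visible as extra labels under vessels.
- **Threshold**: by default `tissue mode - 10 dB`, the midpoint of the
  default 20 dB vessel deficit (the mode is a 0.5 dB-binned histogram mode
  of below-surface voxels within the crop). Before thresholding, a 3 x 3
  lateral (within-depth-plane) mean filter reduces the speckle dB variance
  by ~3x; without it, roughly 15 % of pure-speckle tissue voxels would
  fall below any threshold 8 dB under the mode. An absolute threshold can
  be configured instead.
- **Flatten + crop**: integer per-A-scan shifts (masks stay binary),
  vacated samples zero/False-padded, crop default 500 um of tissue.

## U-Net and training

The network is the symmetric encoder/decoder with skip connections:
encoder blocks of two 3x3 convolutions (ReLU, no normalization layers)
with widths 32/64/128/256 at resolutions 1, 1/2, 1/4, 1/8, a fourth 2x2
max-pool into a 256-channel bottleneck at 1/16, and a decoder of 2x2
transposed convolutions with skip concatenation and paired 3x3
convolutions, ending in a 1x1 convolution to 2 classes. The width stays at
256 through the deepest level; the four poolings force input sizes
divisible by 16 (prediction pads with zeros and crops back). Convolutions
are size-preserving ("same" zero padding) so outputs match B-scan size.

Inputs are 8-bit grayscale B-scans: dB values mapped linearly from
[0, vmax] to [0, 255] (vmax = the volume's 99.9th percentile, fixed per
volume; negatives clip; rounding is round-half-to-even), then scaled to
[0, 1]. Training minimizes the Dice loss of the softmax foreground
probability, `1 - (2*sum(p*t) + 1)/(sum(p) + sum(t) + 1)` with
`eps = 1`, using Adam at learning rate 1e-4 (batch 4, no augmentation).
Per-epoch accuracy is the mean per-B-scan IOU (empty/empty counts as 1);
the best model by validation accuracy is kept. Everything — initialization,
shuffling, splitting — is driven by explicit seeds, and the layers are
implemented directly over numpy (im2col convolutions with explicit
backpropagation), verified against numerical finite-difference gradients.

All data from one volume pass through a single random train/validation/test
split (default fractions 0.5/0.25/0.25, matching the 300/150/150 protocol
at n = 600).

## The scaled study

`octl.pipeline.run_scaled_study` runs the whole experiment at desk scale
on one CPU: a clean training phantom and a held-out phantom (64 B-scans of
128 x 128 each after flattening/cropping; 32 B-scans train the network), a
width-reduced network (8/16/32/64 channels — same architecture, ~300 k
parameters) trained for at most 100 epochs with early stopping once the
training Dice loss reaches 0.05, and a third, heterogeneous phantom with a
75 um / 10 dB superficial layer. Reported quantities: conventional label
IOU against geometric truth, the loss/accuracy histories, the held-out
mean IOU of the network against conventional labels, and superficial vs
deep false-positive fractions for both methods on the heterogeneous
phantom. The layer corrupts the per-A-scan fit (the method assumes depth
homogeneity), so the conventional output shows concentrated superficial
false labels; the network, trained only on clean-phantom labels, does not
reproduce them.

`scripts/acceptance.py` recomputes all of these from scratch for a given
seed and writes them as JSON.

## Known limitations

- The attenuation estimate is biased low by the additive noise floor near
  the window end; the bias grows as surface SNR drops.
- Thresholding quality depends on the vessel deficit exceeding the
  residual speckle spread after lateral averaging; small or faint vessels
  (deficit comparable to ~3x the smoothed speckle sigma) are missed.
- Vessel types (lymphatic vs vein) are rendered and tagged but not
  discriminated by either segmenter.
- The prediction of the size-preserving U-Net is not exactly invariant to
  the amount of zero padding: the bottleneck's receptive field is close to
  global, so predict() always pads minimally to the next multiple of 16.
- Phantom realism limits are listed above; in particular no shadowing and
  no spatially correlated speckle.
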