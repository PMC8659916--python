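# Methods

## The imaging model

`holophase` models an off-axis, image-plane digital holographic microscope
(DHM) operating in the telecentric regime. The camera records the
interference of the object wavefront `o(x, y)` with a tilted plane reference
wave `r(x, y)`:

    h = |r|^2 + |o|^2 + o r* + r o*

The object is a phase object: a field of red blood cells (RBCs) of optical
thickness `t(x, y)` on a flat background, imparting

    phi(x, y) = 2 pi (ns - nm) t(x, y) / lambda0

with defaults `lambda0 = 0.532 um`, `ns = 1.406` (RBC), `nm = 1` (air), and a
camera pitch of 5.86 um behind a 40x objective (0.1465 um at the object).
Note the thickness relation is the standard optical-path-length form; its
inverse `t = phi lambda0 / (2 pi (ns - nm))` is what the thickness module
applies. A cell of peak thickness 0.8 um then peaks 3.836 rad above
background, consistent with reported RBC optical thickness.

Cell profiles are radial: a dome (spherical cap) or a biconcave quartic
`c0 + c2 rho^2 + c4 rho^4` with `(c0, c2, c4) = (0.6, 1.6, -2.2)`, truncated
at zero and rescaled to unit maximum so that the profile peak equals the
specified `max_thickness` exactly. The exact polynomial is a simulator
choice, exposed in `simulate.BICONCAVE_COEFFS`.

Randomly laid-out scenes (`random_scene`) additionally blur the phase map
with a Gaussian of sigma 0.17 um, the approximate point-spread width of the
emulated 0.65-NA objective (~0.21 lambda / NA). This matters physically and
numerically: an ideal truncated quartic has a slope kink at the cell rim
that no diffraction-limited system could image, and whose artificial
high-frequency tail would otherwise dominate the spatial-filtering error.
Bare `SceneSpec` objects default to no blur so closed-form values (peak
phase, thickness round trips) are exact.

Noise model: additive Gaussian intensity noise expressed as a fraction of
the fringe amplitude `2 |r| <|o|>` (default 2%), plus an optional smooth
multiplicative illumination drift across the frame (default 5% peak)
emulating source fluctuations between acquisitions. Speckle and shot noise
are out of scope, as is defocus: all simulated holograms are in focus at the
image plane.

The reference-to-object amplitude ratio defaults to 1:1 (both arms carry the
same power); it is configurable through `ReferenceWaveParams.amplitude`.

## Conventional reconstruction

The pipeline follows the classic two-step Fourier method:

1. **Spatial filtering.** The hologram spectrum (DC-centred FFT) contains a
   conjugate sideband pair carrying `o r*` and `r o*`. The `+1` order is the
   magnitude peak outside a DC exclusion disk (radius `min(N, M)/16`),
   restricted to the half-plane of non-negative row offsets so exactly one
   twin of each pair is eligible. A circular mask (default radius: half the
   sideband-to-DC distance, guarding against zero-order leakage) isolates
   the object band; shifting its peak bin to DC removes the integer-bin part
   of the carrier.
2. **Tilt compensation.** The remaining sub-bin residual carrier
   `(fx, fy)` is cancelled by multiplying with a digital reference wave
   `exp(+2 pi i (fx x + fy y))`. The frequency pair is found by a
   deterministic coarse-to-fine grid search: 3 levels of an 11 x 11 grid,
   initial span +-2 spectral bins, each level spanning one step of the
   previous (final resolution 0.016 bins).

**Search objective.** The classic criterion scores a candidate tilt by
binarizing the [0, 1]-normalized phase at 0.2: a clean compensation
thresholds to an all-white image, a residual tilt to black/white sawtooth
stripes. That count (the TSM) is, however, piecewise constant — it is
exactly flat in a neighbourhood of the optimum where no pixel crosses the
threshold, which is far wider than the final grid step. The search therefore
minimizes

    J(fx, fy) = TSM(phase) + (1 - |mean exp(i phase)|)

The second term — one minus the phasor concentration of the compensated
phase — is smooth, bounded in [0, 1] like the TSM, agrees with it at coarse
scale (a wrapped sawtooth has near-zero concentration), and peaks sharply at
the true carrier, which is what localizes the optimum to sub-step accuracy
(the concentration is the magnitude of the field's off-grid DFT at the
candidate frequency, i.e. a matched filter for the carrier). Phase
normalization is the fixed linear map `(phi + pi) / (2 pi)`; ties break
toward smaller `|(fx, fy)|`. Only a linear tilt is compensated; higher-order
aberrations (astigmatism, coma) are acknowledged but not fitted.

**Twin-sideband sign.** Off-axis holography cannot distinguish `o` from
`o*` without prior knowledge of the tilt direction; picking the other twin
conjugates the phase. The default simulator carrier `(+0.22, -0.22)
cycles/px` places the `o r*` term in the searched half-plane, so simulated
scenes reconstruct with the correct sign; `ReconstructionSettings.conjugate`
flips the sign for data recorded with the opposite tilt. Reconstruction is
equivariant under 90-degree frame rotation (the property rotation
augmentation exploits); 180-degree rotation maps the selected twin onto its
conjugate, and the flag exists for exactly that case.

**Accuracy.** With the default study conditions (4-7 blurred biconcave cells
per 256 x 256 frame, 2% noise, 5% drift) and a mask radius of 60 bins
(~1.5x the blurred cells' band limit, used throughout the end-to-end tests),
piston-free RMSE against the wrapped ground truth is 0.037-0.044 rad across
seeds, and a planted residual carrier is recovered well within one final
grid step. The default half-distance mask (40 bins) trades ~0.03 rad of rim
accuracy for robustness on unknown data.

## Quality metrics

- **TSM** of a [0, 1]-normalized image: `1 - (# pixels strictly > 0.2)/(N M)`
  — the black-pixel fraction after binarization; 0 is distortion-free. The
  threshold comparison is strict: a pixel exactly at 0.2 counts as black.
- **Background STD**: population standard deviation (ddof = 0 — a
  deliberate choice, the region is the full population of interest) inside a
  cell-free region. For batch evaluation the region is auto-selected as the
  32 x 32 corner patch with minimal variance, a stand-in for a hand-picked
  background area. The STD curve is averaged over `std_sample_size = 15`
  images per dataset.
- **RMSE** between two equally normalized images, used for the supervised
  baseline comparison.

## Learning-based reconstruction

The translator is a pix2pix-style conditional GAN, implemented on a compact
numpy convolution engine written for this package (strided conv and
transposed conv via im2col, batch norm, dropout, Adam; every backward pass
is verified against finite differences in the test suite).

- **Generator**: U-Net, 8 encoder convolutions (kernel 4, stride 2,
  filters 64 -> 512) taking 256 x 256 x 3 to a 1 x 1 bottleneck, mirrored
  decoder of transposed convolutions with skip concatenations, dropout 0.5
  on the first four decoder layers, tanh head. Grayscale data are replicated
  across the 3 channels.
- **Discriminator**: six convolutions, strides [2, 2, 2, 2, 1, 1]
  (kernel 4 at stride 2, kernel 3 at stride 1, which is what makes a
  256 x 256 x 6 channel-concatenated pair map to exactly a 16 x 16 score
  map), filters 64 -> 512 -> 1, LeakyReLU(0.2) on the first five layers,
  batch norm on layers 2-5, sigmoid scores. The receptive field of one
  score element under this geometry is 110 px (computed and logged in the
  architecture descriptor rather than asserted).
- **Losses**: discriminator BCE against labels 1/0 (score maps clamped by
  1e-7 inside logs); generator adversarial BCE plus `lambda = 100` times the
  mean L1 distance to the target phase. The heavy L1 weighting is what makes
  early training behave like supervised regression.
- **Optimization**: Adam, lr 0.002, beta1 = 0.5 (customary for this model
  family), batch size 1 by default, 100 epochs. Weight init is
  He/Kaiming-normal, the standard choice for deep conv stacks. Batch norm
  uses batch statistics at inference too (with batch 1 this is instance
  normalization — the standard practice for this architecture); dropout is
  inference-off, so inference is deterministic.
- **Normalization**: holograms map to [-1, 1] by their bit-depth range
  (or the [0, 4] unit-amplitude intensity range for float data); phases by
  (-pi, pi]. Per-image min-max is rejected because it destroys quantitative
  comparability between patches.

**Model selection.** GAN losses oscillate by construction, so checkpoints
are ranked by two per-epoch curves computed from denormalized generator
outputs: mean TSM (phase-discontinuity count) and mean background STD
(noise) on validation data. The selected epoch is the STD minimizer among
epochs at or after the first TSM plateau (|delta TSM| <= tol, default 0.02),
ties to the earliest; if the TSM never plateaus the global STD minimizer is
returned with a warning.

**Desk-scale configuration.** Training the full 256 x 256 / depth-8 / 100
epoch model is supported by the same code path, but the exercised and tested
configuration is scaled down: 64 x 64 patches, depth-6 generator with
filters 16 -> 128, matching discriminator, 200 synthetic training pairs,
batch 4, 5 epochs — chosen so a complete adversarial run takes about two
minutes on one CPU core with this numpy engine. Synthetic pairs at this
scale use 3-4.5 um cells so whole cells fit the 9.4 um field of view, and
the regression target is the wrapped ground-truth phase (standing in for a
conventional reconstruction, which it matches to ~0.04 rad). Under these
conditions validation TSM drops markedly within five epochs and the trained
generator clearly beats the untrained one on held-out patches.

A supervised U-Net baseline (`train_generator_supervised`) reuses the
generator alone with an L1 or logarithmic (pixel-wise BCE) loss.

## What the synthetic generator does not emulate

Real acquisitions include defocused cells, dust, speckle, camera nonlinearity
and mechanical drift between frames; the simulator covers none of these, so
green tests certify the algorithmic pipeline (geometry, spectral bookkeeping,
search convergence, training dynamics), not robustness to real-world
artifacts. Reported real-data image quality and throughput are likewise out
of scope.

## Numerical choices and degenerate inputs

- Wrapped phase lives in (-pi, pi]; `np.angle`'s -pi endpoint is folded up.
- Unwrapping uses a quality-guided path-following unwrapper
  (scikit-image); the branch-cut and quality-guided families agree on
  residue-free inputs, and every unwrap is validated by the exact rewrap
  identity. Residues (non-zero 2 x 2 plaquette loop integrals) are counted
  and reported, not fatal.
- The thickness background level defaults to the median of the
  auto-selected background region, making thickness maps piston-invariant.
- A hologram with no off-axis sideband (peak below 3x the median spectrum
  magnitude outside the DC disk) raises rather than returning garbage.
- Overlapping simulated cells raise: the ground-truth phase of
  interpenetrating cells is ill-posed.
- The sideband mask must lie fully inside the spectrum grid; masks touching
  the DC exclusion disk only warn (zero-order leakage risk).

## Known limitations

- No numerical refocusing: defocused holograms are reconstructed at the
  image plane, wrong for cells off the focal plane.
- Only plane-wave tilt is compensated; curved-wavefront residuals (non-
  telecentric systems) are not.
- The twin-sideband sign convention must be supplied for real data
  (`conjugate` flag); cells are assumed optically denser than the medium.
- The numpy engine is single-threaded per matmul chain and unsuitable for
  full-scale (1512-pair, 100-epoch) training in reasonable time; the
  architecture is faithful, the practical scale is not.
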