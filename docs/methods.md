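# Methods

This note records the models behind each stage, the parameters that
matter, and the numerical and design choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and units

The origin is the geometric focus (center of the sphere the elements lie
on); z points away from the array, so elements sit at negative z.
Positions are in millimetres, times in seconds, the speed of sound `c`
in m/s (default 1540, a standard soft-tissue value; the reconstruction
assumes a homogeneous medium), frequencies in Hz.

## Array model

The physical 256-element arrangement on the cap is not public, so
`build_spherical_array` places elements on equal-area rings with
golden-angle azimuthal increments (a Fibonacci-spiral cap).  The layout
seed only rotates the spiral about the axis — two seeds differ by a
rigid rotation, so no acoustic property depends on it.  Point-spread
behaviour is governed by aperture (57 mm chord on a 40 mm sphere →
receive half-angle ≈ 45°), center frequency (4 MHz) and bandwidth (75%
at −6 dB), not by the exact tiling; the quasi-uniform stand-in is
therefore adequate for resolution work, while element-level effects
(cross-talk, trapezoidal apodization) are out of scope.  An optional
equal-area circular-piston directivity weight is provided but off by
default.

Transmit subsets are chosen by farthest-point (maximin) sampling seeded
with the globally most distant pair; on the 256-element cap the
31-element subset has a ≈ 7.4 mm minimum neighbor spacing, matching the
physical system's sparse transmit pattern.  Acquisition arithmetic is
closed-form: volume rate = 1/(n_tx · PRI); stitched FOV = base +
(n − 1) · step per lateral axis.

## Forward simulation

Propagation is analytic delay-and-attenuate summation; no full-wave
field solver is used, so grating-lobe structure is only qualitatively
representative.

* **PA (one-way).**  Absorbers are impulsive points (the
  nanoparticle-sheet rationale: an optically thin, highly concentrated
  absorber radiates a Dirac-like pressure transient), so each element
  receives the receive impulse response delayed by r/c and scaled by
  absorbed energy × relative absorption at the firing wavelength / r.
  Delays are applied exactly in the frequency domain.
* **US (two-way).**  Per transmit event, each scatterer contributes the
  pulse delayed by (r_tx + r_s→rx)/c and scaled by echogenicity /
  (r_tx · r_rx).  Delays use a pre-computed bank of FFT-phase-shifted
  pulses with 64 sub-sample steps: band-limited interpolation with a
  residual delay quantization of 1/(64 fs) ≈ 0.75 ns (≈ 1 µm of two-way
  path), far below the localization scales of interest.
* **Impulse response.**  A Gaussian-modulated sinusoid
  (`scipy.signal.gausspulse`) whose −6 dB spectral width equals the
  requested fractional bandwidth stands in for the measured response.
* **Noise** is additive white Gaussian per channel, seeded.  No
  frequency-dependent attenuation or aberration is modeled.

Scene builders: `make_flow_phantom` advects bubbles at constant speed
along polylines (step = speed/frame_rate per frame), riding a fixed
random lateral offset within the vessel radius and re-entering at the
start with a fresh offset when they leave the far end, which keeps the
bubble count exactly stationary.  `make_clutter` scatters static
points with exponential echogenicities and an optional sub-wavelength
random walk (per-frame RMS displacement = `jitter_rms`).

What the generator does *not* emulate: nonlinear bubble oscillation,
speckle from unresolved scatterer ensembles (clutter is a finite point
set), tissue motion beyond the random walk, skull aberration, and
frequency-dependent attenuation.  Passing tests therefore demonstrate
correctness of the processing chain under ideal propagation, not
robustness to in vivo physics.

## Beamforming

DAS with two-tap linear temporal interpolation; PA sums real RF one-way,
US sums the analytic signal (one-sided spectrum) over (tx, rx) pairs at
two-way delays and rotates to baseband with a per-voxel reference phase
(round trip via the cap apex) so the IQ carrier is removed; a static
per-voxel phase factor is irrelevant to all slow-time processing.
Output is normalized by the number of contributing channels so
amplitudes are layout-size independent.  Samples outside the record
window contribute zero; the truncated-tap fraction is reported in
`Volume.meta` and > 50% truncation raises an error.  Envelope detection
is the analytic-signal magnitude along depth columns.

The sparse operator assembles exactly the same gather as a CSR matrix
(two nonzeros per voxel-channel pair), so `SparseDAS.apply` agrees with
the direct loops to numerical precision and amortizes delay computation
across slow-time frames.  A memory estimate is checked against a cap
(default 3 GiB) before any allocation.

Conditioning follows the published order for sO2 imaging: Wiener
deconvolution of the receive impulse response (spectrum divided by
|H|² + noise_floor · max|H|²) and a zero-phase low-pass whose −6 dB
point lands at the cutoff (4th-order Butterworth squared by
forward-backward filtering), default cutoff 1 MHz.  Multi-position
volumes are stitched on the voxel lattice with `max` blending by default
(preserves vessels across seam dropout); `mean` is available.

## Spectral unmixing

The shipped extinction table carries the standard tabulated hemoglobin
spectra (OMLC/Prahl compilation) at 700/750/800/850 nm; the 700/750 nm
pair has condition number ≈ 7, and a singular pair is rejected by name.
No fluence compensation is applied — at neighboring NIR wavelengths the
fluence distributions are comparable and any shared positive scale
cancels in the concentration ratio (the unmixing is scale-invariant by
construction).  Voxels below the amplitude threshold (default 10% of
the volume maximum, the in vivo value being unpublished) or with both
concentrations non-positive are flagged invalid and carried as NaN plus
an explicit `valid_mask`; a single negative concentration is clipped to
zero before the ratio, so valid sO2 always lies in [0, 1].

## ULM

* **Motion gating** correlates each frame's lateral maximum-intensity
  projection with the mean MIP; frames below the threshold are flagged,
  not deleted.  The published 99% threshold presumes a projection
  dominated by static anatomy; in small synthetic scenes the moving
  bubbles themselves hold the correlation near 0.985, so the demo
  configuration gates at 0.95.
* **SVD clutter filter** zeroes the largest singular values of each
  block's Casorati matrix (block 600 / remove 150 are the published
  defaults; a final partial block scales the cutoff proportionally,
  floored).  Two artifacts of over-removal, characterized on synthetic
  scenes and relevant to parameter choice: removing more components
  than the clutter rank subtracts part of a slow bubble's path-mean
  field, which (a) carves an artificial dip into the power-Doppler
  profile between closely spaced vessels and (b) biases localizations
  away from a neighboring vessel.  Both scale with the per-voxel bubble
  dwell duty (≈ PSF width / vessel length for recirculating phantoms).
  Synthetic-scene tests therefore match the removal count to the
  constructed clutter rank and use long vessels; in vivo the removal
  count must instead absorb tissue motion.
* **Slow-time filters**: zero-phase Butterworth band-pass per voxel
  (published band 20–107 Hz at 215 Hz volume rate; DC removed), and a
  directional split implemented as quadrant selection in the
  (depth, slow-time) 2D Fourier plane.  The baseband IQ is first
  re-modulated by the two-way carrier exp(+i k0 z), k0 = 4π fc / c:
  without this the Doppler shift −2 fc v_z / c moves a mover's whole
  spectral support to one temporal-frequency side spanning both spatial
  half-planes and quadrant masking cannot separate directions; with it
  the support lies on f = −v k with k > 0 and the quadrants split
  cleanly.  DC and Nyquist planes are shared evenly so the two channels
  sum exactly to the input.
* **Localization**: local maxima above a threshold (given as a fraction
  of the volume maximum, or 3× a MAD-based robust noise floor by
  default) are refined by the 3D radial-symmetry center — the point
  minimizing the gradient-magnitude-weighted squared distance to the
  lines through each window voxel along its intensity gradient, a 3×3
  linear solve per detection.  Near-duplicate detections merge keeping
  the brighter.  Windows are clamped inside the volume; targets should
  stay at least half a window from the grid edge, where clamping biases
  positions.
* **Tracking**: per-frame optimal bipartite assignment
  (`linear_sum_assignment`) with links forbidden beyond
  max_link × frame-gap, gap closing up to `max_gap` missed frames, and
  a minimum track length (defaults max_gap 2, min_length 5; max_link
  should be ≈ 2× the expected per-frame step).  Per-step velocity is
  displacement × frame rate / frame gap.
* **Rendering**: tracks are polyline-interpolated at half-super-voxel
  steps onto a grid `upsample`× finer than the beamforming grid
  (default 4×); density counts deposits, velocity is the
  density-weighted mean speed with NaN (plus a validity mask) where
  undefined.

## Quantification

Vessel segmentation is a deliberately simple morphological stand-in:
Gaussian smooth → threshold (fraction of max) → 26-connected components
→ 3D skeletonization → centerline = the longest shortest path on the
skeleton graph (double-Dijkstra diameter) → radius = mean Euclidean
distance transform along the centerline; length integrates the
centerline polyline and volume = π r² L.  Components of even voxel
width have no center voxel and vanish under thinning; those are retried
after a one-sided dilation, at the cost of at most half a voxel of
centerline bias.  Radius recovery is voxel-quantized (± half a voxel);
length recovery on straight phantoms is within 10%.  Ridge-feature
discriminants (curvature/roundness/ridgeness) of dedicated vessel
extractors are not reproduced; claims rest on phantom recovery.

Functional extraction paints each centerline onto the co-registered
grid, dilates it (default 2 voxels), and averages the finite voxels of
the sO2 / velocity volumes.  Group comparison uses the two-sample
Z-test z = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b) with a two-sided normal
p-value; distributions are summarized by Gaussian KDEs with Scott's
rule (bandwidth factor reported).  The hemisphere split is a
configurable mid-plane.  FWHM measurements interpolate half-maximum
crossings linearly with the profile minimum as baseline.

## Resolution characterization

`pa_point_target_psf` reproduces the crossed-hair measurement
numerically: noiseless PA channel data from a focal point source with
the published parameters (4 MHz, 75% receive bandwidth, 40 mm ROC,
57 mm aperture, c = 1540 m/s, fs = 20.83 MHz), DAS at 60 µm voxels over
4×4×4 mm, envelope detection, FWHM of the lateral and axial profiles
through the peak.  FWHM is read off **intensity** (squared-envelope)
profiles, the standard convention for reported imaging resolution; the
amplitude-envelope FWHM is √2 larger for a Gaussian-like lobe.

## Pipeline and reproducibility

A strict `RunConfig` (unknown keys rejected, schema-versioned) drives
simulate → beamform → so2 / ulm → quantify.  One global seed fans out to
per-stage sub-seeds by CRC32 of the stage name, and per-frame seeds are
stage_seed + frame, so adding a stage never perturbs another's
randomness.  HDF5 datasets are written with `track_times=False` and
volumes as uncompressed NIfTI with a float64 JSON sidecar (NIfTI pixdim
is float32 and cannot carry 0.06 mm exactly), so a rerun from the saved
config is byte-identical; the run log records SHA-256 checksums of every
artifact.  The built-in demo uses a 64-element array, 6 transmits at a
PRI chosen to keep the 215 Hz volume rate, a 3.2×2.4×2.4 mm grid at
0.1 mm voxels, two oblique vessels (so the 10 mm/s flow has an axial
Doppler component inside the slow-time band) and 200 frames — sizes
chosen so the full demo runs in a couple of minutes on one CPU while
exercising every stage.

## Known limitations

Homogeneous speed of sound only; no aberration or attenuation; analytic
point scatterers rather than full-wave fields; the directional filter
assumes the depth axis is the dominant flow axis it separates; tracking
assumes quasi-constant frame-to-frame motion below max_link; vessel
radii are PSF- and voxel-limited when segmenting power-Doppler images;
and the synthetic scenes cannot stand in for in vivo vessel counts or
absolute hemodynamic values.
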