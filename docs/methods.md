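# Methods

## The crowding readout

The package treats steady-state EGFP anisotropy as a proxy for
macromolecular crowding. The physical chain is: crowding raises the local
refractive index n; the radiative rate of a fluorophore scales with n²
(Strickler–Berg), shortening the lifetime τ; the Perrin relation
r = r0/(1 + τ/θC) then raises the measured anisotropy, because the
molecule has less time to rotate before emitting. EGFP is a good crowding
sensor precisely because its rotational correlation time θC (~14–16 ns)
exceeds its lifetime (~2.6 ns): viscosity changes barely move r, so the
lifetime (refractive-index) channel dominates. Homo-FRET acts in the
opposite direction — at high EGFP concentration energy migration
depolarizes emission — which is why the bleach test (r should rise as
intensity falls) is part of the toolkit.

## Anisotropy maps

Per pixel, r = (I∥ − g·I⊥)/(I∥ + 2·g·I⊥). The processing order is fixed:
background subtraction on the full dual-view frame (so both channels lose
background in the correct ratio), the geometric split, registration of the
perpendicular half onto the parallel grid, then the r algebra with the
per-pixel G-factor.

- **G-factor.** g(x,y) = ⟨I∥⟩/⟨I⊥⟩ over a stack of fluorescein reference
  frames (a freely rotating dye has r ≈ 0, so any measured imbalance is
  instrumental). The raw ratio is median-filtered 3×3 to suppress shot
  noise; whether to smooth at all is a genuine design choice and the filter
  is exposed (`median_size=0` disables it). Pixels whose reference
  perpendicular intensity sits below a noise floor are invalidated rather
  than producing unstable ratios.
- **Intensity window.** Pixels are kept when the raw parallel-channel count
  lies in [15,000, 50,000] (16-bit camera): below, shot noise dominates;
  above, the sensor approaches saturation. The gate channel is configurable
  (`threshold_on="total"` windows I∥+2gI⊥ instead); which intensity the
  window applies to is not uniquely determined by the measurement physics,
  so both are offered with the raw parallel channel as default.
- **Modal statistic.** Per cell, the mode of the valid r values is the
  argmax of a Gaussian-kernel density evaluated on a fixed grid
  (r ∈ [0, 0.4], step 1e-4 — spanning the physiological EGFP range
  ~0.16–0.24 with margin; a fixed grid makes modes comparable across cells
  and sessions). Bandwidth defaults to Silverman's rule on the per-cell
  sample and is overridable. The KDE is computed by histogram binning at
  grid resolution followed by convolution with a truncated (±4σ) Gaussian
  kernel — exact to within one grid step and much cheaper than a direct
  n×grid evaluation. Cells with fewer than 200 valid pixels are skipped
  with a logged warning.

## Registration

Bead fiducials are detected as Laplacian-of-Gaussian blobs and refined by
an iterative intensity-weighted centroid in a circular window of ~3σ,
recentered on each iterate (a single large square window lets neighboring
spots pull the centroid by whole pixels; the small recentered window is
accurate to ~0.002 px on clean spots). Correspondences are mutual nearest
neighbors within 20 px; a consensus loop (200 random minimal samples,
1 px inlier band) rejects spurious matches, and the final least-squares
fit is tightened twice around its own residuals (inlier band
max(3·RMS, 0.05 px)) to shed mildly contaminated centroids. The default
transform family is similarity — translation, rotation, isotropic scale —
which covers dual-view optics without assuming shear; affine is available
by flag. Resampling is bilinear; out-of-field pixels are flagged invalid
and excluded from every downstream statistic.

## Photophysics fits

Anisotropy decays are fitted directly on r(t) = r0·exp(−t/θC) with uniform
weights; lifetime decays as A·exp(−t/τ) + offset, tail-fitted from the
peak. Both use bounded least squares seeded from a log-linear fit. A trace
that does not decay within ~100× its window is returned with θC = ∞ and a
`non_rotating` flag instead of a fragile huge number. At realistic photon
budgets (10⁴ peak counts) the late-time r(t) bins carry very few photons;
the synthetic decay window is therefore 0–12 ns (~4.6 lifetimes), beyond
which r is not measurable — with that window the uniform-weight fit is
unbiased to ~2% although single-trace θC scatter remains ~6%.

Phasors are plain discrete sums g = ΣI·cos(ωt)/ΣI, s = ΣI·sin(ωt)/ΣI with
ω defaulting to the first harmonic 2π/T. For a sampled exponential the
leading discretization error is ~ω²τh/2 (h the bin width), which sets the
bin counts used in the verification (≲1e-7 at 400k bins over 30 lifetimes).

## FCS

The model is the standard 3D anomalous-diffusion autocorrelation with
triplet term; α is fixed at 1 and the triplet omitted by default (EGFP in
buffer), S = ωZ/ωXY = 3.633 fixed from geometry. Beam radii follow
ωXY = 0.61λ/NA and ωZ = 2nλ/NA²; radii are interpreted as 1/e² half-axes,
giving Veff = (π/2)^{3/2}·ωXY²·ωZ — the unique standard convention that
reproduces 0.109 fL from (248 nm, 901 nm). Concentration is N/(NA·V), and
D = ωXY²/(4τD) is exposed as a helper.

## FRAP

Recovery of a uniformly bleached disk of radius w follows the closed form
f(t) = e^{−x}[I0(x) + I1(x)], x = 2τD/t, implemented with exponentially
scaled Bessel functions (stable for all x); D = w²/(4τD) and the mobile
fraction is (F∞ − F0)/(1 − F0). The model is isolated in one function
(`disk_recovery`) so an instrument-specific profile can be swapped in. A
fitted plateau below the bleach depth has no diffusive reading and is
returned flagged invalid rather than raising.

## MSD

Time-averaged MSD per track over all ordered pairs, then ensemble mean
across tracks (per-track first, so long tracks do not dominate). Lags are
capped (default: a quarter of the track, or an explicit `max_lag`) because
long-lag estimates average few pairs. The log-log slope is fitted over
0.1–1 s by default, matching the 1 s timescale at which apparent D =
MSD/(4τ) is reported.

## Morphology

Volume = suprathreshold voxels × voxel volume; the height map converts
each column's suprathreshold count to µm, so height·dx·dy sums exactly to
the volume (both count the same voxels — this identity is asserted, not
approximated). The perimeter behind circularity 4πA/P² is the
marching-squares contour smoothed by a 5-vertex circular moving average:
the raw marching-squares polygon of a binary disk overestimates its
perimeter by ~6% (circularity 0.89), while the smoothed contour gives
0.993 for a disk and 0.801 for a square (π/4 = 0.785), leaving straight
edges essentially exact and rounding corners by ~2 px.

Spatial profiles use geodesic distance maps: within the cytoplasm, d_nuc
and d_cell are shortest-path distances (8-connected, diagonal = √2, via
minimum-cost paths) from the nucleus-adjacent and boundary-adjacent
pixels respectively. The normalized coordinate f = d_nuc/(d_nuc + d_cell)
spans exactly [0, 1] between the two boundaries, also in concave cells
where Euclidean distance would tunnel across the exterior. Pixels are
binned into equal-f sectors (default 5: 0–20% … 80–100%) and sector means
are normalized to the innermost (perinuclear) sector — normalizing to the
whole-cell mean was the alternative; the innermost sector is chosen
because the perinuclear region is the natural reference for
center-to-edge gradients, and the normalizer is isolated in one place.

Nuclear fractions are computed on the single Z-plane with the largest
nucleus area: total intensity inside the nucleus over total inside the
cell.

## Osmotic models

Volumes and reciprocal crowding (r_iso/r) are normalized to the isotonic
point and plotted against the pressure ratio x = Π_iso/Π, so both tracks
pass through (1,1) by construction and a one-parameter line
y = 1 + b(x − 1) suffices; the y-intercept 1 − b is the osmotically
inactive volume fraction (volume track) or the limiting reciprocal
anisotropy (crowding track). Osmotic pressure is proxied by total
osmolarity with an isotonic default of 300 mOsm (typical culture medium),
configurable. The dilution law r(V) = (r_iso − α)V_iso/V + α assumes a
conserved crowder number; α follows from any two conditions via
α = (r2V2 − r1V1)/(V2 − V1), and signed deviations from the law are
reported in anisotropy units (conversion to concentration needs a crowder
calibration and is optional). RVI is the percentage volume change between
the post-shock nadir (10 min in the standard protocol) and the final time
point.

## Synthetic data

Every generator inverts its analysis counterpart, so zero-noise datasets
round-trip to the imposed parameters at numerical precision; all
randomness flows through one seeded generator per call (same seed →
identical dataset). Noise models follow the physics: Poisson for
photon-counting modalities, 1% multiplicative Gaussian on the correlation
amplitude (FCS) or the normalized intensity (FRAP). Default parameters are
the study conditions: scenes with r ≈ 0.19–0.22 fields, vignetted
G-factors (1 + 0.1·x/W), media background, a (3.4, −1.7) px channel
shift, 20 beads with 30% spurious additions; FCS at N = 35.714,
τD = 170 µs, S = 3.633 (so the amplitude is exactly 1.028); decays at
r0 = 0.38, θC = 16 ns, τ = 2.6 ns; Brownian tracks at D = 1 µm²/s,
dt = 10 ms; osmotic series at V_iso = 800 µm³, inactive fraction 0.35,
r_iso = 0.20, α = 0.169, excesses 0–600 mM. The channel misalignment is
imposed by cubic-spline shifting of the perpendicular half; registration
resamples it back bilinearly, so the round-trip error on smooth fields is
interpolation-limited (~1e-5 on the fields used) rather than exactly zero.

What the generators deliberately do not emulate: optical blur (no PSF),
camera read noise and gain structure, segmentation errors (masks are
inputs by design), cell-to-cell biological variability beyond what a test
imposes, and multi-exponential photophysics. Passing round trips therefore
validate the computational chain — algebra, registration, fitting,
geometry — not robustness to those instrument effects.

## Problem sizes and verification

The verification suite and `scripts/acceptance.py` use: 128×128 scenes;
100 noisy replicates per fit family (1% noise, or Poisson at 10⁴ peak
counts); 100 Brownian tracks × 10⁴ steps; 5 lifetimes × 400k phasor bins;
a 0.1 µm-voxel sphere phantom (r = 5 µm); 5-condition osmotic series ×
100 replicates at 2% noise. "Within X% over N replicates" recovery
statements are checked on the mean estimate across replicates;
per-replicate maxima are additionally reported and are well inside the
bands for FCS and FRAP, while single-trace θC scatters ~6% at the stated
photon budget (see Photophysics fits).

## Known limitations

- The FRAP disk model assumes an ideal uniform bleach profile and pure 2D
  diffusion; membrane-proximal or anomalous recovery needs a different
  profile function.
- The instrumental scale factor between time-resolved reconstructions and
  wide-field anisotropy is a single free multiplier estimated by least
  squares; it has no independent calibration here.
- Geodesic distances are 8-connected path lengths and overestimate
  Euclidean distances by up to ~8% on diagonals; the normalized coordinate
  f is much less affected because numerator and denominator share the
  metric.
- The modal-r grid [0, 0.4] silently clips samples outside it; fluorophores
  with intrinsically higher anisotropy need a wider grid.
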