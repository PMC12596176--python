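# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `lungqct`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The problem being modelled

Quantitative chest CT compares attenuation statistics across scanners and
protocols, so a harmonization workflow needs (a) a phantom whose regional
ground truth is known, (b) image-quality estimators (densitometry, MTF,
NPS), and (c) a decision rule that turns the measurements into a protocol
choice. The package implements all three; because no public image archive
exists for the physical phantom, a synthetic phantom module provides
simulated scans whose ground truth is exact.

## Synthetic phantom

**Scope of the simulation.** The simulator is a *linear blur + correlated
noise* model. Beam hardening, scatter, polychromatic spectra, tube-current
modulation profiles and vendor reconstruction algorithms are deliberately
not modelled: the artifact under test is the analysis chain, and every
downstream metric responds only to the blur kernel, the noise magnitude and
the noise correlation, all of which are explicit parameters. Consequently,
passing tests demonstrate estimator correctness on data satisfying the
linear model — they do not certify behaviour under scanner-specific
nonlinear effects (e.g. scatter-induced HU bias in air, which real
multi-scanner data exhibits).

**Geometry.** Body: an ellipse of 435 × 229 mm (left-right ×
anterior-posterior, chest plates included) of 35 HU tissue, centred on the
origin. Two elliptical foam lungs (−629.2 HU nominal, 29 HU texture)
contain three tubes running the length of the chest cavity: one large tube
(inner radius 23 mm) in the right lung and two small tubes (inner radius
14 mm, anterior and posterior) in the left lung, with 60 HU walls. Inserts
stack along each tube in 40 mm slots with 5 mm gaps. The tube positions,
slot layout and per-configuration insert assignments are package-defined
constants: the physical phantom's internal blueprint is not public, so
these are a modelling choice, not a reproduction.

**Materials.** Air and water use the densitometric ground-truth values
(−1000 and 0 HU). Foam and lung-sample nominal HUs mirror a modern
reference reconstruction (NIST foams −934.0 … −683.0 HU; lung sample
−655.6 HU with 130 HU texture; lung foam −629.2 HU). Structural plastics
(HDPE −70, urethane 60, acrylic 120, PMP −180, synthetic bone 148/570,
low-contrast epoxy 15 HU) are typical CT numbers chosen once.

**Texture.** Heterogeneous materials receive a seeded Gaussian field
smoothed with a 1 mm kernel and renormalized to *exact* mean 0 and the
stated SD over the region. This makes per-region ground truth (mean, SD,
LAA percentages) computable by brute force on the noiseless volume, which
is how the oracle tests work. With a 130 HU texture SD the lung-sample
region yields LAA950 of roughly 1–2% — the clinically relevant low range.

**Acquisition model.** Scans are the noiseless volume convolved with a
separable Gaussian PSF (defaults σ_xy = 0.52 mm, σ_z = 0.54 mm, the widths
whose analytic 50% cutoffs sit near the observed reference values of ~3.6
and ~3.5 cycles/cm), plus noise: seeded white Gaussian noise filtered by a
3×3×3 stencil normalized to unit sum of squares (variance preserving) and
scaled so a uniform region has SD = `noise_sd_at_reference` ·
sqrt(reference_ctdi / ctdi_vol) — the standard quantum-noise dose relation.
Defaults anchor to the reference protocol: 15.4 HU at 2.22 mGy.

**Grids.** The default reconstruction geometry is 0.51 × 0.51 mm in-plane
(512² grid ≈ 260 mm field of view, tight to the ribcage — the chest plates
are cropped laterally, as in a tight clinical FOV) with 0.5 mm slice
spacing; the z extent auto-fits the configuration. The test suite runs most
image tests at 1.02 × 1.02 × 1.5 mm on 256² grids — the package's choice of
desk-scale problem size — and uses the native 0.51 mm pitch wherever
sampling geometry matters (all MTF work, the end-to-end comparison).

## Segmentation

The approach is transparent template alignment rather than an attempt to
reproduce any proprietary pipeline: threshold at −300 HU → largest
component = body; per-slice hole filling → interior; the two largest low-HU
interior components are the lungs (tube walls separate tube air from foam).
The in-plane translation between layout and scan comes from the body
centroid; the axial shift from correlating observed tube-core HU profiles
with the layout's expected material profile. Insert masks are then carved
geometrically from the aligned layout and eroded by a margin (default
1 mm ≈ 2 in-plane voxels) to exclude walls and partial-volume voxels;
`segment_lungs` accepts the same margin (2 mm removes the ~4 HU
partial-volume bias of the raw threshold mask). An insert whose measured
mean is >250 HU from its material nominal is reported missing and the rest
are returned (degraded mode). The construction is deterministic and exactly
equivariant under whole-voxel phantom translations, which the tests assert
literally.

## Densitometry

Sample SD (n−1 denominator; fixed so oracle tests are exact).
CoV = SD/|mean| — the absolute value is required for air ROIs whose mean is
negative but whose published CoV is positive. LAA uses strict `<` at
−950/−856 HU. One published CoV entry (water vial 1, 6.87) differs from the
ratio of its own published mean and SD (26.2/3.8 = 6.89) because the source
evidently divided unrounded machine values; the package computes from full
precision and the tests carry a ±0.05 tolerance for that comparison.

## MTF estimation

Pipeline: per exposed cube face, ESF → central-difference LSF → Hann window
→ |FFT|, normalized to 1 at zero frequency, cutoffs by linear interpolation
at the first downward crossing, frequencies in cycles/cm. In-plane = the
pointwise mean of the x- and y-face modulation on a common frequency grid,
with cutoffs recomputed on the averaged curve (averaging curves rather than
cutoffs is a package choice; the alternative is not distinguishable from
published summaries).

**ESF estimator.** Rays are cast along the grid axis nearest the face
normal and read *raw* voxel values. Each ray's half-height crossing is
estimated; a plane is fitted to the crossings over the face (the edge is
planar, so this suppresses per-ray jitter); samples are re-centred by the
fitted crossing, pooled across rays, and binned at 0.1 × voxel pitch
(empty bins filled by linear interpolation). This is the classic
oblique-edge super-resolution construction: because the cube sits ~3° off
the grid, ray phases tile the voxel pitch and the pooled samples resolve
the edge far beyond single-ray Nyquist. The alternative — spline-resampling
each ray at fine pitch — was measured to lose ~30% modulation near Nyquist
(the cardinal-spline transfer function), which would bias the 20% cutoff of
a sharp (σ = 0.3 mm) system by far more than the few-percent target; raw
pooling has only the 0.1-pitch binning box filter (<0.5% at the highest
cutoff tested).

**Profile reach and window.** The profile extends an adaptive distance
(≈ 4 mm + 10·σ̂ from a pilot width estimate, clamped to the geometry — 15 mm
default, 11 mm inside the phantom where the tube wall limits the air gap)
to either side of the edge. The Hann window spans the full profile centred
on the LSF peak; with too short a profile the window truncates wide LSFs
and biases cutoffs upward (+10% at σ = 1.2 mm for a ±7 mm profile), which
is why the reach adapts. Verified accuracy on exactly-blurred cubes
(erf closed form, so the simulation itself has zero blur discretization):
worst-case cutoff error ≤ 2% for σ ∈ {0.3, 0.5, 0.8, 1.2} mm at 0 and
15 HU noise.

**Cube pose.** The cube region is re-thresholded at half height between
the cube and air plateaus; the end cap (same material, glued to one z
face) is separated by its per-slice area signature (a disc much wider than
the cube) before the centroid and half-edge (cube root of the thresholded
volume) are computed; the capped face is excluded from measurement.
Cube-likeness is enforced by requiring the three axis spreads to agree
within 20%.

## Noise power spectrum

In-plane: non-overlapping 64² patches per slice of a uniform region, 2-D
polynomial detrend (default order 2), |DFT|² scaled by (Δx·Δy)/(Nx·Ny)
(units HU²·mm²), averaged, radially binned at one DFT bin. z-direction:
non-overlapping 32-slice column segments, 1-D detrend, Δz/Nz scaling
(HU²·mm). With these scalings the spectrum integrates to the detrended
variance (Parseval), asserted to 5% in tests. Peak frequency uses parabolic
sub-bin refinement; a curve whose maximum is within 1.25× of its median
power is flagged flat (white noise) and reported as 0. No apodization is
applied: the shape tests construct patch-periodic noise fields so that
periodogram leakage cannot confound the |H(f)|² comparison, which is the
honest way to validate the estimator at the few-percent level.

## Dose arithmetic and protocol selection

Effective dose E = CTDIvol · scan length · k with defaults 30 cm and
0.027 mSv·mGy⁻¹·cm⁻¹ (chest conversion factor). Full precision is carried
internally; display rounding is half-away-from-zero (2 decimals for mSv,
integers for %). Recomputing the bundled protocol table's effective-dose
column reproduces 10 of its 12 printed values exactly; the two exceptions
(7.44 → 6.0264 printed as 6.02, and one of two 3.50 rows printed as 2.85
while the other prints 2.84) are internally inconsistent with any single
rounding rule and are flagged rather than matched.

Selection: stage 1 scores each candidate by total |Δmean HU| vs the
reference over the primary inserts (air, water vial 1, water vial 2 — the
materials with exact ground truth) and by an MTF score (mean of the four
cutoffs); a candidate that uniquely minimizes ΔHU (no rival within
`hu_tie_tol`, default 5 HU) and maximizes MTF (within `mtf_tie_tol`,
default 0.1 cycles/cm) wins outright. Otherwise stage 2 picks the
HU-acceptable candidate with the lowest summed HU SD (image noise). The
tolerances are explicit configuration because the underlying procedure
publishes none; the defaults are the scale of differences its worked
example treats as ties. Exact SD ties fall back to lexicographic candidate
name so the rule is total and order-invariant (asserted by permutation
tests and a brute-force oracle).

## Known limitations

* The simulator's linearity means scanner-specific HU bias mechanisms
  (scatter, beam hardening, kernel nonlinearity) are out of scope; the
  published per-scanner MTF/HU values are not reproducible from synthetic
  data and are not claimed.
* Discrete Gaussian filtering in `simulate_scan` differs from continuous
  convolution near Nyquist (sampled-kernel aliasing), so MTF accuracy
  claims are made against the erf-exact cube volumes; in-phantom MTF runs
  carry a ~1–6% discretization imprint from the simulator itself at
  coarse z spacing.
* Segmentation assumes the declared configuration matches the scan and
  recovers translation only (plus an axial shift); rotations of the phantom
  are not modelled, matching the iso-centred acquisition procedure.
* The z-direction NPS requires columns fully inside the mask over ≥ 32
  slices; irregular masks with shorter runs are rejected rather than
  silently padded.
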