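# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic benchmark does and does not establish
about real fibrescope data.

## Synthetic comb model

A comb mask C(x, y) ∈ [0, 1] is the per-pixel transmission of the fibre
bundle. Fibrelets sit on a hexagonal lattice of pitch (D + g)·M — D the
mean fibrelet diameter, g the cladding gap, M the magnification, which
scales cores and cladding together on a fixed-size sensor — with uniform
positional jitter (disc of radius `position_jitter`·pitch) and per-fibrelet
radius jitter. Each fibrelet is a disc, Gaussian-blurred (default σ = 1 px)
to emulate soft fibrelet edges, and clipped to its Voronoi cell. The
Voronoi clipping keeps fibrelet supports disjoint under jitter and gives
the irregular fibrelet outlines seen in real bundles; it also makes the
decomposition C = Σᵢ Cᵢ exact by construction. Defaults: D = 8 px,
g = 2 px, jitters 0.08/0.12, on a 512 px frame ≈ 2500 fibrelets at pitch
10 px — about the density of a 10⁴-fibrelet bundle imaged across a
10³-pixel sensor.

Fibre sampling: for each fibrelet the scene mean Mᵢ over the binarised
support Cᵢ > 0.1 (strict, fixed) is painted back through the graded mask,
Iˢⁱᵐ = Σᵢ Cᵢ·Mᵢ, then additive Gaussian noise. Default noise σ = 2.55
counts = 1% of an 8-bit dynamic range — a plausible camera noise floor;
the choice matters mostly for centre-finding recovery and for
interpolation, which reads one pixel per fibrelet and is therefore the
method most sensitive to it.

### CFA sampling and the dark level

The nine-band mosaic capture picks band P(x, y) at each pixel and adds a
sensor dark level (default 2 counts ≈ 1%) before noise. The dark level is
what makes cladding pixels carry a small spectrally flat signal, as they do
on any real sensor (dark current, stray light). It is essential to the
spectral-fidelity comparison: with an exactly black cladding, every
mean-preserving correction would reconstruct the scene spectrum perfectly
up to noise and the spectral metric could not separate the methods. With
it, reconstructions that mix cladding pixels into the spectra (all
demosaick-then-filter variants dilute the per-band signal by the ~0.4 fill
factor before the flat offset is added) flatten the measured spectrum
roughly twice as much as centre-based interpolation, which samples bright
cores — reproducing the expected ordering for a physical reason, not a
tuned one.

### Test targets

- *Bar charts*: vertical square-wave gratings, one strip per
  (spacing, phase), default spacings {16, 22, 32, 45, 64, 90, 128} px — a
  geometric series spanning ~0.8–6.4× the default comb's Nyquist spacing
  (2 × 10 px pitch), i.e. the range over which correction methods actually
  differ — with 3 phase-staggered strips per spacing. Levels 0/200, blurred
  by σ = 1 px (target imperfection).
- *Flat field*: constant 150 for smoothness.
- *Bright region*: 156 on a 117 background for signal, ROI inset inside the
  region.
- *Scene spectra* come from synthetic calibration tables on a 450–900 nm
  grid: Gaussian band responses at the eight narrow-band centres
  (553–829 nm, 30 nm FWHM) plus a smooth-edged 500–850 nm broadband;
  sources are a 630 nm LED (flat-field/spectral fixture), a flat white
  spectrum (calibration frames) and a far-red fluorophore emission
  (signal fixture). E^k = Σ_λ G·R^k is both the generator's scene spectrum
  and the ground truth of the spectral-accuracy metric, so Q measures
  corruption introduced by the correction alone.

## Centre finding

Neighbourhood size D must be odd (2d+1) and close to the fibrelet
diameter; the quasi-Gaussian exponent uses the full D, not d. Candidates
need a neighbourhood intensity range above I_min; candidates whose
neighbourhood leaves the frame are discarded (a truncated neighbourhood
would bias the score), which sacrifices a one-radius border. Score ties
are broken in raster order; the greedy exclusion is strictly > D. The
vectorised scorer expands the residual sum into two correlations and is
tested against the direct per-candidate formula; the greedy map is tested
against an O(n²) reference.

Two practical notes. First, recovery of *all* planted centres is only
possible when adjacent true centres are more than one exclusion diameter
apart; the recovery fixtures therefore use gap 3 px and position jitter
0.08 (minimum spacing ≈ 9.2 px > D = 9). Second, on combs that stop short
of the frame edge the dark rim produces isolated accepted candidates just
outside the bundle; they satisfy the exclusion rule and only affect the
outermost ring of the interpolated image.

For mosaic calibration frames a Gaussian pre-blur suppresses the CFA
pattern first; default σ = L/2 (1.5 px for the 3×3 sensor) — anything
above ~L/3 works, the choice is uncritical.

## Corrections

- Spatial filters use symmetric (mirror) boundary handling.
- The median window is 2r exactly; even windows have no centre pixel, so
  the window is anchored with the output pixel in its top-left quadrant
  and the median of an even sample is the upper order statistic (rank
  filter, no mid-pair averaging).
- The Fourier "crop" is a radial (circular) pass-band by default, chosen
  for isotropy; a square per-axis cut is selectable. The DC component is
  always kept.
- r is accepted in [1, 50] px inclusive. It is nominally dimensionless but
  is used in pixel units throughout.
- Scattered interpolation precomputes the Delaunay triangulation, simplex
  indices and barycentric weights once per centre set and grid; the same
  lookup table serves every band, which is what makes per-band and
  shared-table multispectral interpolation bitwise identical. Outside the
  convex hull pixels take the nearest centre's value and are flagged in a
  validity mask. Centre values are single nearest-pixel reads by default
  (matching the one-pixel-per-fibrelet readout); a 3×3 mean is available.
- Nearest-band-neighbour ties (possible for even L) are averaged — the
  deterministic one of the two sanctioned options (average vs randomised
  pick).

## Resolution metric

Michelson contrast per bar element is estimated from the row-averaged
profile, comparing means over the central thirds of ideal bar and space
positions — unbiased under noise and residual comb, unlike profile
max/min. Contrasts of the phase-staggered elements sharing a spacing are
averaged *with sign*: the aliasing beat between bars and fibre lattice is
phase-dependent and cancels, genuinely resolved contrast is
phase-independent and survives. Without this, sub-Nyquist beat reads as
several percent contrast and the 5% crossing lands below the physical
sampling limit.

R is the 5% crossing of a cubic smoothing spline through contrast vs
spacing (threshold 5% rather than 1% to stay above the noise floor), with
the smoothing factor chosen by leave-one-out cross-validation over a small
grid (fallback stiffness 0.01·n·var). If the contrast never drops below 5%
the target limits the measurement and R is the smallest spacing; if fewer
than 4 distinct spacings show contrast above 1% no spline is fitted and R
is undefined. Undefined R enters the score normalisation as the comparison
set's R_max (score 0). Several methods hitting the target/sampling floor
tie at the smallest spacing; ties in the winner map resolve in the fixed
order interpolation, fourier, gaussian, median, physical, then ascending r.

Smoothness is the population standard deviation; resolution is in pixels
(µm only when a physical scale is configured). Multispectral R and σ are
band averages; S averages the bands overlapping the fluorophore emission
(665 nm, 714 nm, broadband).

## Benchmark and weight sweep

One benchmark run generates the comb and the three fixtures, builds the
centre map once from a bright-field calibration frame, applies every
(method, r) variant — monochrome grid r ∈ {2, 3, 5, 8, 12, 16, 20, 25},
multispectral grid {1, 5, 10, 25}, defocus displacements
{1, 2.5, 5, 10} µm with a Gaussian defocus PSF of 1 px/µm (the defocus
PSF is otherwise uncharacterised) — and normalises min-max within that
run. Scores are therefore not comparable across runs, and the run manifest
says so. The simplex grid step defaults to 0.01 for three active weights
and 0.05 for four; winner-region statements are grid-resolution-robust
(refining the grid never changes a coarse point's winner) but region
*boundaries* are only resolved to the grid step.

Problem sizes: the reference benchmarks run at 512² with ~2500 fibrelets;
a monochrome run takes ~1 minute and a multispectral run a few minutes on
one core, dominated by the large-window median filters.

## What the synthetic benchmark does not show

The generator reproduces irregular comb geometry, fibre-mean sampling,
mosaic interleaving, additive noise and a dark floor. It does not model
inter-fibrelet crosstalk, vignetting, chromatic variation of fibrelet
transmission, wavelength-dependent PSFs, or the non-Gaussian noise of real
sensors; defocus is an idealised Gaussian blur, and magnification scales
cores and cladding together, which real bundles need not do. Passing
trends here show the pipeline's logic and the methods' relative behaviour
under controlled conditions; absolute metric values on real endoscope
frames will differ. Edge-enhancing demosaicking and compound corrections
(e.g. interpolation followed by smoothing) are out of scope.
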