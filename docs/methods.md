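# Methods

`ecsnano` quantifies the nanoscale organization of the brain extracellular
space (ECS) from two kinds of data: movies of single rod-shaped
near-infrared emitters (single-walled carbon nanotubes, SWCNTs) diffusing
through live-tissue ECS, and binary segmentations of cryofixation electron
micrographs. This note describes the models, the estimators, their
parameters and the choices made where the procedure admitted more than one
reasonable implementation.

## Coordinate and unit conventions

Continuous positions are in nanometres with the origin at the field
corner; a raster index (row, col) maps to continuous coordinates with
(0, 0) at the centre of the top-left pixel (`x_nm = col * pixel_size`,
`y_nm = row * pixel_size`). Times are in seconds, diffusion coefficients
in nm²/s unless a value is explicitly printed in m²/s.

## Single-probe localization

Emitters are fitted with a rotated asymmetric 2D Gaussian (seven
parameters: position, major/minor sigma, orientation, amplitude, flat
background) by trust-region nonlinear least squares, initialized from the
fit window's intensity moments. Three consecutive frames (30 ms exposure)
are averaged in a *sliding* window before each fit; output frames keep the
central frame's timestamp. Sliding (rather than block) averaging preserves
the 30 ms sampling that the 90 ms MSD fit needs, at the cost of serial
correlation between consecutive localizations — which is why MSD fits
start at a lag of one full sampling interval and use a free intercept.

Fits are rejected when the optimizer fails, the window is flat, the
amplitude is below 2× the local background sd, the major sigma exceeds
half the fit window, or (optionally) the residual rms exceeds a
configurable fraction of the amplitude. These rejection thresholds and the
15 px default fit window are package configuration, not values taken from
any reference; they were chosen so that a well-exposed single emitter on a
64×64 px field is essentially always accepted.

`gaussian_crb_xy` provides the shot-noise (Poisson) Cramér–Rao position
bound for the same seven-parameter model, computed numerically from the
Fisher information; the test suite checks that the Monte-Carlo RMSE of the
fit stays within 1.5× this bound at a 10⁴-photon budget.

## Drift correction (redundant cross-correlation)

For a region of the movie containing only static background structure, the
shift between every ordered frame pair (t, u) is measured as the argmax of
their cross-correlation, refined per axis with a three-point quadratic
interpolation. The T(T−1)/2 shifts form an overdetermined linear system
Δ_{t,u} = r_u − r_t for the per-frame drift r (gauge r_1 = 0), solved in
the least-squares sense; equations with a 2D residual above 1 px are
flagged as outliers and removed, iterating until the set stabilizes
(outlier sets grow monotonically, so termination is guaranteed; hard cap
100 iterations). A disconnected non-outlier equation graph is an error
naming the disconnected frame groups, never silently interpolated.
The solution is smoothed with a 5-frame moving average weighted by each
frame's non-outlier equation count and re-pinned at r_1 = 0. The window
length is configuration; the weighting rule is part of the method.

Two caveats are documented deliberately. First, the three-point parabola
is accurate to <0.1 px only when the correlation peak is a few pixels wide
(background feature scale ≲1.5 px of blur); very smooth scenes bias the
interpolation. Second, the correlated region must not contain the moving
probe — in the bundled pipeline an automatic ROI takes the widest
horizontal strip outside the probe's explored bounding box.

## Trajectory building

Localizations are linked frame-to-frame by greedy nearest-neighbour
assignment in ascending distance order under a 500 nm step cap (≈3σ of a
30 ms displacement at the largest instantaneous diffusivities seen in
tissue), with a 3-frame memory for missed detections and a 20-point
minimum track length. Global-optimal assignment is out of scope; at
tissue probe densities the greedy rule is equivalent in practice.

Probe length L is estimated in "quiet" frames (displacement to the next
frame <40 nm): the apparent major-axis FWHM is deconvolved from the
optical FWHM in quadrature and reduced by the ~100 nm exciton diffusion
length — the apparent elongation of a nanotube's emission profile — then
floored at zero and summarized by the median. Fewer than 5 quiet frames
leave L undefined; such trajectories later use the cohort median length.

Immobile probes plateau in their global MSD. The classifier calls a track
immobile when the log-log MSD slope over lags [4·dt, span/4] is below 0.2
or the plateau ratio MSD(span/2)/MSD(4·dt) is below 2. The thresholds are
declared configuration validated on simulations (confined 50 nm box and
pure localization noise → immobile; free Brownian → mobile).

## Instantaneous diffusivity and relative diffusivity

The instantaneous MSD is computed over a sliding 450 ms window (15 samples
at 30 ms), time-averaged over all index pairs at each realized lag; a
straight line with free intercept is fitted to lags ≤90 ms and
D_inst = slope/4 (2D tracking), floored at 0 with a flag. The free
intercept absorbs static and averaging-induced localization error.
Pooled over windows, the *median* of this estimator on free Brownian
motion is intrinsically ≈8% below the true D (the window estimator is
right-skewed; its mean is unbiased). This bias is a property of the
prescribed estimator, measured on simulation in the acceptance script.

The reference free diffusion of a rod of length L and diameter d (aspect
ratio φ = L/d) in a fluid of viscosity η at temperature T is

    D_ref = 3 k_B T ln(2 φ) / (8 π η L)

evaluated with the exact SI Boltzmann constant. Defaults: T = 310.15 K
(recording temperature), η = 0.70 mPa·s (water at 37 °C, a
cerebrospinal-fluid-like reference viscosity; configuration), d = 1 nm.
For L = 500 nm this gives D_ref ≈ 1.01×10⁻¹¹ m²/s. Relative diffusivity
D_inst/D_ref is reported per window at the window centroid.

## Super-resolved maps

Localizations (density mode) or per-window values (mean-value mode) are
rendered on 25 nm pixels as 2D Gaussians of 50 nm FWHM and unit amplitude.
Density maps sum the kernels; value maps use normalized convolution
(value-weighted kernel sum over kernel sum), so map values are convex
combinations of the inputs and never overshoot; pixels without support are
NaN. Exploration areas are the count of density-map pixels ≥0.5 (the
kernel's half maximum) times the pixel area, in µm².

## Local ECS width from confinement

Along each mobile trajectory, sliding 6-point windows are summarized by
their second-moment ellipse; the eccentricity ratio is the minor over
major peak-to-peak extent of the window's points projected on the
principal axes. Windows at maximum confinement — the lowest quartile of
the ratio within each trajectory — carry the width signal. The width
estimate is

    width = C · sqrt(max(minor_extent² − (c_n · σ_loc)², 0))

with a calibration factor C = 2.066 frozen from a one-time calibration on
simulated reflecting channels of 50/100/200 nm width
(`calibrate_width_factor` reproduces it), and an effective noise
coefficient c_n = 1.35 measured the same way (the selection favours
low-noise windows, so the naive iid order-statistics coefficient 2.53
over-corrects). For 6 independent uniform positions the expected range
would be 5/7 of the channel width (factor 1.4); the larger frozen factor
reflects that Brownian window positions are correlated and that the
lowest-quartile selection keeps the smallest extents. Recovery on held-out
simulations is within 20% for 50–200 nm channels, with and without 30 nm
localization noise.

Because the selection deliberately keeps the most confined windows, width
estimates on *unconfined* motion are a fraction of the 6-point window's
diffusion span; the documented sanity floor is the single-interval
diffusion length sqrt(4 D dt), and the estimator is only meaningful where
motion is actually confined. Width and diffusivity recover their own
ground truths independently; no correlation between them is asserted.

## EM-mask morphometry

* **Volume fraction**: foreground over total pixel count.
* **Compartment lengths**: per 8-connected component, the skeleton's
  longest shortest path (graph diameter; orthogonal steps 1 px, diagonal
  √2 px), exact all-pairs shortest paths up to 4000 skeleton pixels and a
  double-sweep bound beyond (exact on trees, which thin skeletons almost
  always are). Converted to µm with the 1.42 nm EM pixel size.
* **Local thickness**: for every foreground pixel, the diameter of the
  largest inscribed disc containing it. The disc radius at candidate
  centre q is EDT(q) − ½ (boundary at pixel edges, so a k-pixel slab reads
  exactly k); dominated centres (a neighbour's disc provably covers
  theirs) are pruned, leaving distance-ridge points, and the computation
  matches an exhaustive brute-force search exactly.
* **Width categories**: channels [0, 100) nm, small pools [100, 200] nm,
  large pools (200, ∞) nm, as percentages of ECS pixels. The 100 nm and
  200 nm boundary points are assigned to small pools by convention.
* **Category comparison**: Pearson chi-square on the 2×3 count table
  (df = 2), valid when all expected counts are ≥1.

Components touching the image border are analyzed as-is but flagged,
since EM fields are crops of larger tissue.

## Matrix-network morphometry and statistics

Stained-area fraction uses Otsu's automatic threshold (method id is
configuration) after optional background-reference subtraction (clipped at
zero) and optional ROI masking. Box-counting dimension uses box sizes in
powers of two from 2 px to a quarter of the image side on a single grid
origin — a documented, reproducible convention; multi-offset minimization
is deliberately not performed. Cable lengths delegate to the skeleton
longest-shortest-path machinery. The optical fractionator estimate is the
exact arithmetic N = ΣQ⁻ × 1/ssf × 1/asf × t/h, reported raw and rounded.
The two-sample Kolmogorov–Smirnov test compares cumulative distributions
with an exact p-value for small samples (n·m ≤ 10⁴) and the asymptotic
approximation for large ones. Distribution summaries report relative
frequency or ECDF tables with median and IQR under the
linear-interpolation quartile convention.

## Synthetic ground truth

The generator produces every structure the analysis assumes:

* **Geometry**: channels-and-pools scenes — circular pools (widths
  100–300 nm) chain-connected by straight channels (<100 nm wide), the
  regime reported for brain ECS; connectivity holds by construction.
* **Probe motion**: reflected Brownian motion with locally varying D;
  specular reflection against the rasterized boundary (normal from the
  signed distance field), re-applied up to 8 times, with a
  Metropolis-style rejection fallback that preserves the uniform
  equilibrium density. Probe orientation follows the channel axis inside
  channels and diffuses rotationally in pools — a declared stand-in, as
  rod-probe rotation in tissue is not characterized.
* **Rendering**: the emitter is an asymmetric Gaussian whose minor FWHM is
  the optical PSF (default 400 nm) and whose major FWHM adds the probe
  length plus the 100 nm exciton elongation in quadrature; EM-CCD noise is
  Poisson shot noise, then Gaussian read noise, then gain. Optional dim
  static background spots emulate the stationary tissue features drift
  correction requires.
* **Masks**: Voronoi cell-packing gaps of uniform nominal width, or
  rasterized pool geometries, bisected to a target ECS fraction within
  0.5 percentage points (15–24% is the physiological range); the nominal
  width field is recorded as truth.
* **Fractal references**: line (D_b = 1), filled square (D_b = 2) and the
  Sierpinski triangle (D_b = log 3/log 2 ≈ 1.585).

What the generator does **not** emulate: photophysics (blinking,
bleaching — nanotube emitters are effectively non-bleaching), multi-probe
overlap, 3D geometry, anisotropic optical aberrations, or structured
tissue autofluorescence. Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to be
statistically decisive at desk scale: 100 trajectories of 450 steps for
the pooled D_inst recovery (≈44,000 windows, so the pooled median reflects
the estimator's intrinsic value rather than sampling noise), 50 frames /
1225 equations for drift recovery, 5 seeds × 800 steps per channel width,
25–50 random 64×64 masks for the exact morphometry oracles. Randomness is
always drawn from explicit seeds; reruns are bit-identical. Degenerate
inputs (flat fit windows, empty masks, all-isotropic window sets,
disconnected drift graphs, zero marginals) raise explicit errors rather
than returning silent defaults.

## Known limitations

* The tissue-data headline numbers (median relative diffusivities, width
  medians, volume fractions, fractal dimensions of stained networks)
  depend on animal tissue and are not reproduced here; the package
  validates the estimators by parameter recovery on synthetic truth.
* Quadratic peak interpolation degrades on very smooth correlation peaks.
* The width calibration factor is validated only against this package's
  own walker model; probes with different flexibility or steric
  interactions would need recalibration.
* Box-counting uses one grid origin; absolute D_b values for arbitrary
  images can shift by a few hundredths under other conventions.
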