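# Methods

`alphadose` computes small-scale (sub-organ) absorbed dose rates from
single-particle digital autoradiographs of sequential thin tissue sections
labelled with the alpha emitter ²¹¹At, and estimates absorbed dose from
dose-rate kinetics across biopsies. This note records the models, the
numerical choices, and what the synthetic phantoms do and do not demonstrate.

## Physical model

**Decay chain.** ²¹¹At (T½ = 7.2 h) emits one alpha per decay under secular
equilibrium with its daughter ²¹¹Po: either the direct 5.87 MeV alpha
(branch fraction 0.418 by default) or the 7.45 MeV ²¹¹Po alpha following
electron capture (0.582). The branch fractions are configurable
(`NuclideData`); the electron-capture X-ray/Auger contribution is not
modelled. Detection efficiency defaults to 0.49 — half of the 98% 4π
scintillator efficiency, since a tissue slice mounted on the screen exposes
only 2π.

**Stopping power and ranges.** Transport uses the continuous slowing down
approximation (CSDA) with a packaged total stopping-power table for alpha
particles in liquid water. The table follows a Geiger-rule power law
R(E) = k·Eᵖ (p ≈ 1.583, k ≈ 2.915 µm·MeV⁻ᵖ) calibrated so that the CSDA
ranges of the two chain alphas match their published values in water —
48 µm at 5.87 MeV and 70 µm at 7.45 MeV. This gives a physically shaped
S(E) (≈ 78 keV/µm at 5.87 MeV, rising toward low energy, i.e. a Bragg peak
at track end) while anchoring the quantities that matter for 12-µm
sectioning dosimetry: how many neighbouring slices an alpha can reach.
The table covers 0.005–10 MeV; interpolation is log-log (exact for a power
law). Quadrature of 1/S(E) from the 0.01 MeV cutoff reproduces the anchor
ranges to 0.002 µm. Swapping the CSV swaps the medium; no interface
corrections are attempted (dose-point-kernel methods are ill-posed for
heterogeneous microstructure).

**Monte Carlo kernel.** The energy-deposition kernel K is the mean energy
per source emission deposited in 1-µm voxels of a 151³ grid centred on the
emission point, from 10⁷ sampled emissions by default (seconds of runtime;
the transport inner loop is numba-compiled). Each emission samples a branch
and an isotropic direction; the track is a straight ray from the central
voxel's centre. Deposition is explicit-Euler: S(E)·Δs per step
(Δs = min(voxel/5, 0.2 µm)) at the step midpoint, with the entire residual
deposited at the track endpoint, so per-track energy conservation is exact
and ΣK equals the branch-weighted mean initial energy (6.790 MeV) to
float precision. There is no energy-loss straggling, angular scattering or
delta-ray transport: alpha tracks in water are nearly straight, and the
simplification keeps the kernel reproducible at desk scale. Two
consequences worth knowing:

* the radial profile has *sharp* Bragg peaks — the profile rises just below
  48 and 70 µm instead of the smeared bumps a condensed-history code
  produces, and cuts off abruptly;
* Euler stepping overshoots the quadrature range by ≲ 0.2 µm, so a
  near-empty radial shell exists at 71 µm whose statistical noise is large
  relative to its tiny mean.

Per-voxel statistical uncertainty is the standard error of the per-emission
mean, from accumulated per-event sums and sums of squares (per-event deposits
into a voxel are merged before squaring).

**Radial averaging and rebinning.** Voxels are grouped into 1-voxel-wide
spherical shells by centre distance (half-open bins) and replaced by the
shell mean, which preserves ΣK exactly and enforces the isotropy the physics
implies. The shell value's uncertainty is the pooled standard error of the
mean, √(Σσᵢ²)/M. Note the summary statistic "mean relative uncertainty over
non-zero voxels" is then dominated by the 71-µm edge shell (≈ 0.33% at 10⁷
events; the typical interior shell is ≈ 0.03%), while without pooling the
per-voxel mean is ≈ 7% — the quantity is convention-sensitive and both
conventions are exposed. Rebinning to acquisition geometry (XY 10–30 µm,
Z 12 µm) sums constituent fine voxels (energy is extensive), requires
integer voxel ratios, and keeps an odd-sized, centred grid. At 12-µm slices
all deposition ends within ±6 slices (72 µm ≥ the 70-µm maximum range).

## Image pipeline

**Listmode.** Camera frames are thresholded; pixels ≥ threshold are grouped
by 8-connectivity, and each component of ≥ 2 pixels (single-pixel noise is
rejected) becomes one event at its intensity-weighted centroid. Overlapping
clusters are not split. Coordinates are 0-based, origin top-left,
x = column, half-open pixels; all modules share this convention.

**Activity.** Each slice ROI (Otsu-segmented connected component, reading
order) gets a temporal count histogram (600 s bins by default) fit with
N(t) = A·e^(−λt) by least squares; the per-ROI λ is shared by all pixels
(per-pixel statistics are too sparse). Counts convert to activity at the
biopsy reference time by A = N·λ·e^(λ·t_start)/(ε·(1 − e^(−λT))). When a
rate fit is impossible (near-empty slice) the pipeline falls back to the
nuclide λ = ln 2/7.2 h.

**Registration.** Consecutive 12-µm slices are treated as minimally
distorted rigid 2-D transforms of their neighbours and chained: slice k is
aligned to the already-transformed slice k−1 by an exhaustive MSE rotation
scan (1° default) followed by Powell refinement of (θ, dx, dy) on a
two-level pyramid with bilinear warps, refinement bounded to ±5° around the
coarse angle. Bilinear interpolation slightly changes each slice's total;
the recorded compensation factor Σbefore/Σafter is multiplied back so
cumulative activity is conserved exactly (≤ 1e-6 relative by construction).
Torn or discarded slices are replaced by a copy of the nearest good
neighbour (ties to the lower index), and an even slice count is reduced by
dropping the last slice so a central slice exists. Rigid only within a
stack; shear is reserved for histology fusion.

**Dose rate.** The dose-rate map is the zero-padded FFT convolution of the
activity stack (Bq/voxel = emissions/s under secular equilibrium) with the
rebinned kernel, divided by the voxel mass evaluated at the voxel where dose
is scored (standard dose-point-kernel practice; the displayed source/target
labelling in the field's convolution notation is ambiguous, and scoring mass
at the dose voxel is the physically meaningful choice for uniform water
anyway). Units: MeV → J via 1.602176634e-13, reported in mGy/h. Tiny
negative FFT round-off is clipped to zero. Analyses use the central slice
only, because peripheral slices lack measured tissue across the full alpha
range on one side.

**Uniformity.** Tissue is masked at one-tenth of the Otsu threshold of the
dose-rate map (relative, so intensity scale drops out), closed, hole-filled,
largest component kept. Pre-smoothing is off by default: dose maps are
already smooth, and smoothing dilates hard phantom boundaries enough to
spoil sub-pixel mask accuracy. The masked map is partitioned by the
population mean and σ (ddof = 0): cold < mean+1σ ≤ mid < mean+2σ ≤ hot,
half-open so a value exactly at a threshold goes to the upper region.

**Kinetics.** Region-mean dose rates versus time post-injection are fit with
y(t) = a·e^(−b(t−m)) − c·e^(−d(t−n)) by weighted least squares (weights
1/error²), initialised from the data maximum and the physical decay constant
with 5 seeded restarts. Note (a, m) and (c, n) are structurally
non-identifiable — only a·e^(bm) is determined — so goodness is judged on
the fitted curve, not raw parameters. Absorbed dose integrates the curve
from t = 0 (injection) to six half-lives (43.2 h, capturing 1 − 2⁻⁶ ≈ 98.4%
of a pure-decay integral) by fine trapezoid, clipping negative early-time
values to zero. A rough one-sided uncertainty scales the curve through the
maximum observed point: (s − 1) × dose, floored at zero.

**Limited-slice methods.** With only N = 1, 3, 5, … central slices measured:
*slice contribution* convolves the truncated stack and rescales the
central-slice total Ḋ_N by C_N = 1/ratio(N), where ratio(N) is fit with the
asymptotic model 1 − α·e^(−β(N−1)) on a fully sampled reference stack
(ratio(∞) = 1, C₁ finite; the model form is this package's choice — an
asymptotic exponential loses accuracy once the data already sit at unity);
*cloning* pads the outermost measured slices outward to span the kernel's z
half-extent (⌈70/12⌉ = 6 slices each side) before convolving. Cloning is
exact for depth-uniform activity and biased in the direction of the central
slice's contrast with its neighbours: features only in the measured slice
are over-weighted (hot centre → overestimate, cold centre → underestimate).

**Histology fusion.** Both images are cast to binaries — Otsu on the
inverted-luminance H&E (tissue darker than background), one-tenth Otsu on
the sparser dose map so the whole tissue extent is covered — brought to a
common µm/px scale from their pixel-size metadata (the high-resolution H&E
is processed at a 20× down-sample), registered by the same coarse-MSE +
rigid refinement, with optional shear (|shear| ≤ 0.2; the stained section
lies 50–100 µm from the measured slice) and a manual reflection flag for
face-down slices. The composite transform is returned in full-resolution
H&E coordinates; Dice overlap < 0.5 flags low confidence.

## Synthetic phantoms

The generator emulates what the pipeline assumes about real acquisitions: a
lymph-node-like ellipsoid of uniform background activity with isotropic
Gaussian hot foci (the simplest model of focal uptake sufficient to exercise
σ-partitioning and cloning bias); Poisson event counts with the exact
truncated-exponential decay time law; 20 µm FWHM Gaussian detector blur plus
uniform within-voxel dither; per-slice rigid jitter (U(−10°, 10°),
U(−20, 20) px by default — large enough to exercise the coarse search);
torn slices as zeroed random half-plane wedges. It does **not** model real
lymph-node microarchitecture, slice-to-slice anatomical change, camera gain
structure, cluster-shape statistics, or deformable section distortion — so
passing tests demonstrate correct inference under the pipeline's stated
assumptions, not robustness to anatomy that violates them.

## Problem sizes and tolerances

Default test phantoms are 24–72 px across with 3–9 slices and minutes-scale
simulated acquisitions (10³–10⁵ events per slice); kernels in tests use
2×10⁴–4×10⁵ emissions, and the full-statistics checks use 10⁷. Monte Carlo
coverage checks use 40–60 seeded repeats. Oracle equivalences (FFT vs direct
summation, radial average vs exhaustive grouping) are asserted at 1e-9
relative; conservation laws (per-track energy, activity through
registration) at 1e-6 or better; statistical recoveries at 3 standard
errors. Registration accuracy targets are 0.5°/0.5 px on centred asymmetric
phantoms — a coarse rotation-only scan can confound rotation with
translation for far-off-centre content, which is a real limitation of
MSE-rotation initialisation, not of the refinement.

## Known limitations

* No straggling/scattering in the kernel: sharp Bragg structure, and
  statistical-uncertainty summaries differ from condensed-history codes.
* DPK convolution assumes homogeneous water-density tissue.
* Chained rigid registration accumulates no systematic drift on phantoms but
  has no loop-closure; strongly dissimilar neighbouring slices can mislead
  the MSE criterion.
* The double-exponential integral is sensitive to the sparse early-time
  sampling; the max-scaled bound is a heuristic, not a confidence interval.
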