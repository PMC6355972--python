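# Methods

`cellvol3d` quantifies how cells cultured inside 3D hydrogels change size and
state: it measures single-cell volume, surface area and sphericity from
confocal membrane-dye stacks, nuclear:cytoplasmic (N:C) ratios of
transcription factors (RUNX2, YAP) from DAPI/phalloidin/target stainings,
relative intracellular calcium from Fluo-3/Fura-red dye pairs, peri-cellular
matrix enrichment from fluorescent-alginate images, hydrogel viscoelasticity
from compression traces, and the osmotic pressure applied by PEG-400 dosing.
Every measurement is validated against synthetic phantoms whose ground truth
is analytic, so the whole pipeline runs and is testable with no experimental
data.

## Morphometry model

A single cell is segmented from the membrane-dye channel as the
26-connected supra-threshold component (26-connectivity keeps thin
protrusions attached; 6-connectivity fragments them).  The default
threshold is Otsu's (minimum intra-class variance); the
`otsu_plus_k_sd` variant raises it by `k` global intensity SDs to probe
threshold sensitivity — since supra-threshold sets nest, volume is provably
monotone non-increasing in `k`, and the relative change across `k` is the
reported robustness metric.  Holes are filled per z-slice before
measurement because membrane dyes label the surface more than the interior
while voxel-count volumes presume solid objects.

* **Volume** `V` = number of labelled voxels × `dz·dy·dx` (µm³).
* **Surface area** `A` = triangle-summed area of a marching-cubes
  iso-surface at level 0.5 of the binary field after a Gaussian pre-smooth
  of σ = 0.2 µm (expressed in physical units, so anisotropic spacing is
  handled).  Meshing the raw binary overestimates a sphere's area by
  ~8–12% (staircase artifact), which would bias sphericity far below the
  sphere-equals-1 anchor; a digitization study across r = 2.5–7.5 µm
  spheres at 0.2-µm isotropic and (0.4, 0.2, 0.2) µm spacings showed
  σ = 0.2 µm holds |area error| under ~1.5% for spheres while keeping a
  10-µm cube within 5% of its true area.  Larger σ progressively erodes
  sharp shapes.
* **Sphericity** Ψ = π^(1/3)·(6V)^(2/3)/A, which is 1 for a sphere and
  tends to 0 for a line.  Digitization can push measured values slightly
  above 1; the accepted mesh allowance is +0.02.

Quality flags rather than silent exclusion: components touching the image
frame (`touches_border`), components within one voxel of another label or
showing a fused-pair signature (`touches_other_cell`), and sub-minimum
components (default 65 µm³, a ~2.5 µm-radius sphere — debris rejection is
explicit and configurable).  Flagged cells stay in the output table; only
summary statistics exclude them, mirroring the practice of analysing single
cells not in contact with others.  The fused-pair signature is an EDT neck
test: two comparable-depth maxima of the physical-units distance transform
whose connecting segment dips below 0.8× the shallower peak.  A thin
protrusion only produces a shallow secondary peak (excluded by the 0.6
relative-depth cutoff) and an elongated single body has a flat ridge, so
neither is flagged; validated on sphere, 1:1:3 ellipsoid, protrusion and
fused-pair phantoms.

## Localization model

Nucleus = Otsu(DAPI), cell = Otsu(phalloidin), cytoplasm = cell minus
nucleus, nucleus clipped to the cell.  The N:C ratio is the ratio of
compartment **means** — mean target intensity over the nuclear area (2D) or
volume (3D) divided by the mean over the non-nuclear cytoplasm — not the
mean of per-pixel ratios.  No background subtraction by default (an
optional corner-region estimator exists).  2D analysis operates on a single
focal plane; pass a projection explicitly if wanted.  Multi-nucleus masks
keep the largest component and are flagged.  Because both compartment
means are spacing-free, the ratio is invariant to voxel-size metadata and
to any global intensity scaling.

## Ratiometric readouts

*Calcium*: mean(Fluo-3)/mean(Fura-red) over the cell mask.  This is a
relative readout only — it is never calibrated to molar concentration.
Cells whose Fura-red mean falls below 5× the out-of-mask background SD are
flagged invalid, never silently dropped.

*Matrix accumulation*: mean alginate intensity in the 0–3 µm shell outside
the cell border divided by the background 30 µm away.  "At 30 µm" is
operationalized as the 28–32 µm distance shell (half-width configurable)
because a measure-zero contour contains no pixels; distances come from a
Euclidean distance transform with physical sampling.  The 3-µm band is
exterior-only (cell-interior pixels are excluded) — a declared choice.
Pixels inside other cells are excluded from the background shell, and a
cell whose shell leaves the frame is an error naming the cell.

## Mechanics and osmotics

The initial elastic modulus is the least-squares slope of the stress–strain
curve restricted to the 5–10% strain window (kPa per unit strain).  The
relaxation half-time τ½ is the first time at which the hold-phase stress
crosses half its initial value σ0, with σ0 taken at the first hold sample
(not the ramp peak) and the crossing linearly interpolated between samples
so the estimate is independent of the sampling grid.  Traces that never
halve report `None` together with the final stress fraction.

PEG-400 osmotic pressure uses the empirical quartic
y(atm) = 0.00002c⁴ − 0.0007c³ + 0.0311c² + 0.5596c (c in % wt/vol),
converted at 101.325 kPa/atm; the coefficients are kept verbatim at their
published precision and never refitted.  On c ∈ [0, 6] the polynomial is
strictly increasing and convex, and reproduces the working dose table
(1.5, 3, 6% → 92, 197, 441 kPa after integer rounding).  Osmolarity treats
PEG 400 as a single 400 g/mol osmolyte, giving 25·c mOsm/L (37.5/75/150 at
the same doses).  Hypoosmotic treatment by diluting medium with a water
fraction w scales osmolarity by 1 − w.

## Statistics

ALP-positive fractions carry exact (Clopper–Pearson) binomial CIs.
Spearman's rank correlation uses mid-ranks for ties; its p-value is an
exact full-permutation enumeration for n ≤ 10 and the t approximation with
n − 2 df above.  Volume–response trends are fitted either as ordinary
least squares or as the saturating form r(V) = a·V/(k+V) by nonlinear
least squares initialized at a = max(r), k = median(V); both forms are
exposed because the functional form of the published trend was never
stated, and no claim is made about which the original analysis used.
Group comparisons are the standard two-sample t and one-way ANOVA with
Bonferroni-adjusted pairwise follow-up.

## Phantom generator

Phantoms are digitized by the voxel-center rule on grids with physical
spacing; the default (0.4, 0.2, 0.2) µm reproduces a 0.4-µm z-interval
confocal acquisition and exercises anisotropy by default.  Noise is
additive Gaussian clipped at zero (default SD 10 on a ~100–200 count
scale, i.e. 5–10% of signal — a declared choice, since real-image noise
statistics are instrument-specific); Poisson shot noise is an option, not
the default.  What each phantom guarantees:

* **Sphere** (bead analog, 1-µm/15-µm nominal diameters map to r = 0.5/7.5
  µm): V = 4/3πr³, A = 4πr², Ψ = 1.  Voxel-count volume converges to the
  analytic value as spacing shrinks; at 0.2 µm isotropic the error is
  below 2% for r ≥ 2.5 µm.
* **Protrusion**: sphere of radius R with a capped cylindrical arm of
  radius r and exposed length L along +x.  The cylinder base sits flush at
  the inscribed plane x₀ = √(R²−r²) and its buried length is extended by
  exactly the volume of the spherical cap beyond that plane divided by
  πr², so the union volume is exactly 4/3πR³ + πr²L + 2/3πr³ and the union
  area is 4πR² − 2πR(R−x₀) + 2πr·L_cyl + 2πr².  The truth is analytic by
  construction, never itself voxel-based.  L = 0 degenerates to the plain
  sphere (no cap term).
* **N:C cell**: concentric nucleus/cell with prescribed compartment
  intensities; truth ratio = nuc/cyto.  2D and 3D modes share geometry, so
  a mid-slice 2D measurement and the 3D measurement agree on the
  radially-symmetric phantom.
* **Accumulation**: uniform gel at a background level with the 0–3 µm
  exterior shell multiplied by `band_fold`; truth ratio = `band_fold`.
  The generator refuses images too small to hold the 30-µm background
  shell.
* **Calcium**: Fluo-3 = ratio × Fura-red inside the cell; a
  zero-Fura-red phantom is a declared degenerate case flagged invalid.
* **Relaxation traces**: elastic ramp at 0.005 strain/s to a 15% hold, then
  10⁴ s of hold sampled at 1 s.  Maxwell σ0·e^(−t/τ) (τ½ = τ·ln2), SLS
  σ0·(p+(1−p)e^(−t/τ)) (τ½ = τ·ln((1−p)/(0.5−p)) for p < 0.5, otherwise
  none), or purely elastic.
* **Population**: per-cell volumes lognormal per condition, marker
  positivity Bernoulli(g(V)) with a monotone link shared across
  conditions.  Default conditions — volume means (6000, 2500, 900) µm³
  with CVs (0.50, 0.45, 0.35) for expansion-permissive / intermediate /
  restricted arms — reflect a cell of ~12 µm initial diameter (~900 µm³)
  expanding severalfold when the matrix permits, spanning the few-hundred
  to few-thousand µm³ range over which differentiation readouts vary.
  Default link: saturating with a = 0.6, k = 2000 µm³.

What the phantoms deliberately do **not** emulate: point-spread-function
blur, photobleaching, depth-dependent attenuation, textured intracellular
staining, or crowded multi-cell fields beyond the two-sphere contact case.
Passing phantom tests therefore demonstrates correctness of the
measurement definitions and their numerical implementation, not robustness
to every optical artifact of real microscopy.

## Identifiability of the saturating link

With binary per-cell outcomes, the (a, k) pair of the saturating link is
weakly identified at desk-scale sample sizes: across repeated populations
of 300–1500 cells the median error on k from binned percent-positive fits
is 20–30%, because binomial noise and the strong a–k correlation trade off
along the likelihood ridge.  Parameter-level recovery to 10% is
demonstrated where it is statistically attainable — percent-scale
responses with ~5% noise at 100 design points — while the Bernoulli
population is tested for what it can support: a positive, significant
rank correlation between volume and positivity and curve-level (fitted
percent at the median volume) agreement with the generating link.

## Problem sizes and numerical choices

Default test-suite problem sizes — spheres up to r = 7.5 µm at 0.2 µm
isotropic (~90³ voxel stacks), 50 phantom replicates per N:C truth, 300-cell
populations — are chosen so the full suite completes in well under a minute
while leaving every tolerance comfortably non-trivial; all scale linearly
if larger runs are wanted.  Ties in Otsu thresholding follow
scikit-image's histogram convention (256 bins).  Tables are written with
floats fixed at 6 significant digits so identical seeds reproduce
byte-identical CSVs.  The pipeline's global seed fans out to stages via
`SeedSequence(seed, spawn_key=(stage_index,))`, so inserting a stage never
reshuffles another stage's randomness.

## Known limitations

Segmentation is threshold-based; heavily textured membrane staining or
low-contrast images would need pre-filtering that the package does not
provide.  The fused-pair flag is a heuristic tuned to convex-ish cell
bodies.  Surface areas of objects thinner than two voxels along any axis
are flagged degenerate and should not be trusted.  The 2D N:C analysis
assumes the chosen focal plane intersects both compartments.  Osmotic
calculations are specific to PEG 400 and the published concentration range
(0–6% wt/vol); extrapolation beyond it is unvalidated.
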