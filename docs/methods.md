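# Methods notes

This note records the models, parameter choices, numerical conventions,
and validation logic behind `macuquant`, in the order the pipeline runs.

## Region geometry

All regional measures live on a square raster with an isotropic mm scale
and a (possibly fractional) fovea center. A pixel belongs to a region iff
its center does, and radial intervals are half-open `[inner, outer)`, so
the six rings C1–C6 (outer diameters 0.92, 1.23, 1.55, 1.87, 2.18,
2.50 mm) partition the total annular zone (TAZ, 0.60–2.50 mm) exactly,
pixel for pixel — the identity "TAZ density = area-weighted mean of ring
densities" holds in exact pixel arithmetic, not approximately. The ring
diameters are equally spaced in diameter (increments 0.155–0.16 mm), not
equal in area. Quadrant sectors are bounded by the 45° diagonals; 0° is
image-up and angles increase clockwise. Temporal/nasal assignment assumes
fundus display orientation (temporal on the left for right eyes) and is a
config flag (`temporal_side_od/os`) because display conventions vary.

Mask areas converge to the analytic annulus areas as resolution grows
(tested at 304 and 1024 px over a 3 mm field: the 1024² TAZ area is
within 0.1% of π(1.25² − 0.30²) mm²).

## Layer segmentation

Boundaries are modeled as left-to-right paths through a cost raster, one
row per column, with vertical moves between adjacent columns bounded by
`max_step` (default 2 px). The cost is derived from the vertical backward
difference of the lightly smoothed image: with the backward difference the
gradient peak falls exactly on the first row of the deeper layer, so a
noise-free phantom is recovered with zero error rather than a
half-pixel-convention offset. Smoothing is anisotropic (default σ = 1 px
axially, 3 px laterally): boundaries run laterally, so a wider lateral
kernel suppresses speckle without displacing edges. Cost is mapped
linearly to (0, 1] and kept strictly positive so cumulative cost is
monotone in path length; the dynamic program breaks ties toward the
smaller row index, making results bit-reproducible. The program is tested
against exhaustive enumeration of all feasible paths on small instances
(≤ 8 columns, ≤ 12 rows, 100 seeded cases — exact agreement including
tie-breaks).

The nine boundaries are traced sequentially: the inner limiting membrane
first (strongest dark→bright edge), the outer retinal boundary next, then
interior boundaries in decreasing saliency (order `1 9 5 2 3 7 4 6 8` for
the default polarity pattern), each search confined between its
already-found neighbours with a 3 px margin per intervening boundary.
The margin matters: with a 1 px margin a weak boundary's search band
reaches into the blurred shoulder of a strong neighbour's edge and locks
onto it. Non-crossing therefore holds by construction and is also
asserted. The polarity/order table is configuration, not hard-coded,
since the anatomical contrast pattern depends on the device's rendering.

Ocular magnification: the lateral scale is multiplied by
q(AL)/q(AL_ref) with q(AL) = 0.01306·(AL − 1.82) (Bennett's abbreviated
formula); the reference length defaults to 23.95 mm and axial lengths
outside (15, 35) mm are rejected.

Thickness maps: each of 18 meridional profiles (radial scans over 180°,
fovea at the midpoint) contributes a half-meridian every 10°; each map
pixel is interpolated linearly between the two angularly adjacent
half-meridians and linearly along radius. Pixels beyond the scanned
extent are NaN and excluded from regional means, never imputed. Reported
layers are NFL (boundaries 1–2), GCL+IPL (2–3), GCC (1–3), INL+ORL (3–9,
i.e. total minus GCC), and total retina (1–9); GCC = NFL + GCL+IPL holds
to machine precision because it is the same boundary arithmetic.

Validation: on seeded nine-layer phantoms with parallel sinusoidal
boundaries, Gaussian blur σ = 1 px and multiplicative speckle up to
SD 0.25, every boundary's mean absolute error stays below 1 px (the
acceptance bar is 2 px at speckle SD 0.2); regional thickness means are
recovered within 3 μm at 3 μm/px axial sampling.

## Capillary density

The chain: SSI > 40 gate (strict) → bicubic upsampling 304² → 1024²
(≈ 2.93 μm/px at a 3 mm field) → noise floor = mean + k·SD (k = 2) of the
flow signal inside the **fixed** 0.60 mm central disk → large vessels =
pixels above 3× the noise floor whose connected component has skeleton
width ≥ 25 μm → all vessels = pixels strictly above their local mean
(window 0.20 mm) minus an offset (3 grey levels), union-enforced to
contain the large-vessel map → capillaries = exact set difference →
regional density = 100 × |capillary ∩ region| / |region|.

Conventions worth stating: the fixed 0.60 mm disk (not the detected FAZ
contour) defines both the noise-floor region and the TAZ exclusion — the
detected contour is reported as metadata only. Large-vessel pixels are
excluded from the density numerator but remain in the denominator
("proportion of the measured area"); `rcd_numerator: all` switches the
numerator to all vessels. All thresholds compare strictly, and all
regional geometry lives on the 1024² grid, so identical input and
configuration give bit-identical maps.

The adaptive window (0.20 mm) and offset (3 grey levels on an 8-bit
scale) were fixed by calibration against phantom ground truth: the window
must be much larger than the intercapillary correlation length (or the
local mean tracks the mesh itself) but small against the FAZ (or the dark
center depresses thresholds ring-wide); the small positive offset centers
the recovery error across the 50–80% density range, compensating the
asymmetric edge cut a pure local-mean threshold makes at densities away
from 50%. With these defaults, across 50 seeded phantoms spanning true
densities 0.50–0.80 the TAZ density error has mean ≈ +0.9 pp and a 95th
percentile of |error| ≈ 3.8 pp. A local-mean threshold is intrinsically
density-dependent near large vessels (their brightness lifts the local
mean and suppresses neighbouring capillary detection); this is a property
of the algorithm, reproduced — not hidden — by the phantoms.

FAZ detection: the central 1.2 mm window is grayscale-closed with a
0.044 mm disk — this fills the dark intercapillary gaps, which otherwise
form a web connected to the FAZ through which a region-based level set
leaks, while preserving the large avascular zone and the terminal
capillary ring that delimits it — then lightly smoothed; Canny edges seed
an initial contour radius and a morphological Chan–Vese level set (80
iterations, curvature smoothing 2) converges to the interface. The
region containing the center is kept if its area lies in
[0.01, 1.5] mm² and it is clearly darker than its surround (contrast
≥ 15% of the window's intensity span); otherwise a fixed 0.60 mm disk is
returned with a warning. Chan–Vese is our choice of level set; an
edge-based geodesic contour was evaluated and under-grew on noisy
phantoms. Phantom accuracy: area within ~3% for disks and within 7% for
elliptical and mildly irregular shapes.

## Cohort statistics

Eyes cluster within patients, so eye-level test statistics must not
assume independence. The package reports: eye-level group means ± SD, a
plain one-way ANOVA (reference only), a patient-clustered robust Wald
test of the overall group effect, and pairwise comparisons that default
to **Welch t-tests on patient means**. With one or two eyes per patient,
averaging eyes within a patient removes the dependence exactly; in null
simulations at the study's cluster structure (1,000–2,000 replicates)
these tests reject at 4.7–5.4% for nominal 5% and 1.0–1.4% for nominal
1%, whereas cluster-robust Wald tests from the eye-level fit (CR1 or
Bell–McCaffrey CR2 alike) rejected at 6.5–7.0% — over the ±2 pp
calibration bar we impose. The cluster-robust pairwise variant remains
available (`pairwise_method="cluster_robust"`). The family significance
level for the thickness and density panels is α = 0.01 (multiple-testing
rule); α = 0.05 elsewhere.

ROC: the empirical AUC is the Mann–Whitney statistic (ties counted half),
oriented to be ≥ 0.5 with the direction recorded — thickness and density
both *decrease* in disease, so orientation matters. The binormal AUC
Φ(|μ₁−μ₂|/√(σ₁²+σ₂²)) serves as a closed-form cross-check computable from
group summaries alone. The composite index fits a two-predictor logistic
regression by maximum likelihood (ridge-penalized fallback on separation,
flagged), takes the empirical AUC of the fitted probabilities, finds the
Youden-optimal probability cutoff, and reports one cutoff per component:
the component value at the operating point with the other component at
its sample mean — a deliberate interpretation, switchable in principle to
probability-cutoff reporting. Note the in-sample composite AUC is *not*
mathematically guaranteed to reach the better marginal AUC (likelihood,
not AUC, is optimized); shortfalls beyond 0.02 never occurred in 100
seeded cohorts and the median improvement is positive.

Pearson correlations pool the two patient (non-control) groups' eyes
(n = 74 at the default design). The iid Fisher confidence interval is
used; with bilateral clustering it under-covers slightly (~90% observed
for nominal 95% at inter-eye correlation 0.6) — an accepted
approximation, noted here because the cohort generator can quantify it.

## Synthetic data

*B-scan phantoms* render eight layers between nine parametric boundary
curves (flat, parallel sinusoid, or a foveal-pit-like central depression)
at distinct mean intensities chosen to alternate bright/dark as in a
conventionally displayed B-scan, then apply Gaussian blur and
multiplicative speckle. Truth boundaries are returned alongside.

*Angiogram phantoms* are built on the 1024² analysis grid: a zero-flow
FAZ (disk, ellipse, or mildly irregular), a terminal capillary ring
(30 μm) delimiting it — real foveae are bounded by such a ring; without
it the first capillary would sit a random gap-width beyond the nominal
boundary and the boundary would be unobservable to any algorithm — a few
large vessels as smooth bright arcs (2 by default, widths 25–30 μm), and
a capillary mesh modeled as a thresholded band-limited Gaussian random
field (correlation 10 px ≈ 30 μm). The mesh threshold is calibrated per
ring by field quantile, so each ring's realized capillary fraction
(large-vessel pixels counted in the denominator, as the density measure
does) equals the target; the TAZ and sectors follow by aggregation. The
intensity tiers (background 40 ± 4, correlated; capillary +85; large
vessel +130 on an 8-bit scale) emulate decorrelation contrast in which
the dual-threshold algorithm is well-posed: the capillary level lies
below 3× the noise floor and the large vessels above it, mirroring how
arterioles render brighter than capillaries in en face angiograms. The
device raster is produced by *sampling* the scene at the 304² pixel
centers (the instrument measures one decorrelation value per raster
pixel); area-averaging would wash out the capillary/background
bimodality that real angiograms retain. What the phantoms do **not**
model: projection and motion artifacts, vessel-shadowing, signal falloff,
real capillary network topology (only area fraction is controlled).
Passing recovery tests therefore demonstrates the algorithm chain is
unbiased against its own geometric ground truth, not device-level
accuracy on patient images.

*Cohorts* draw one row per eye. Group means/SDs default to the reference
thickness and density tables; each measure's value is
μ + σ(√ρ·z_patient + √(1−ρ)·z_eye) with inter-eye correlation ρ = 0.6
shared latent patient effects (ρ is a free parameter — no published value
exists for it). The designated pair (GCC TAZ thickness, superficial TAZ
density) shares correlated latent components at both levels, giving the
target marginal correlation 0.312 within groups; pooling the two patient
groups leaves it essentially unchanged (their means are close), while
pooling with controls inflates it (~0.42) through the between-group mean
structure. GCC is drawn at its own printed moments rather than as
NFL + GCL+IPL: enforcing additivity would change the GCC variance away
from the printed SD, and the printed marginals are the conditions being
emulated. Values are truncated at zero (negligible at these coefficients
of variation). About 65% of eyes come from bilateral patients (74 eyes
from 44 patients in the reference design implies ≈ 68%).

## Problem sizes and determinism

Default validation sizes: 100 oracle instances for the path search; 50
angiogram phantoms for density recovery; 1,000 null cohorts for test
calibration; 10,000 eyes per class for the large-sample AUC agreement;
18-meridian phantom eyes for end-to-end checks. Every stochastic
component takes an explicit seed (`numpy.random.default_rng`), all
thresholds compare strictly, and ties break deterministically, so
identical seed + configuration yields byte-identical records and report
files; the cohort report writes a manifest with a content hash of the
configuration.
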