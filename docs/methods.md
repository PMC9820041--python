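# Methods

## Analysis grid and spatial primitives

The analysis unit is a square cell on a regular, axis-aligned planar
grid (nominally 5 km on a side).  Cell membership is half-open,
`[x, x+s) × [y, y+s)`, so point-to-cell binning is a true partition:
every finite point maps to exactly one cell or is counted (never
silently dropped) as out of bounds.  Raster fields with their own,
finer resolution are aggregated to cells by the pixel-center rule —
each pixel contributes to exactly one cell — which conserves raster
mass whenever the raster tiles the grid.  Both conventions are choices
the data do not dictate; they were fixed for determinism and mass
conservation rather than to match any particular GIS default.

The east/west stratification uses a straight line through two
endpoints.  A point is "east" iff the 2-D cross product
`(b − a) × (p − a)` is ≤ 0 — the right-hand side of the line oriented
a → b — with on-line points deterministically east.  The default
endpoints run Tengchong (98.497°E, 25.020°N) → Heihe (127.528°E,
50.245°N), i.e. south-to-north, which under this sign rule places the
densely populated side of China on the east.  In lon/lat the "line" is
a straight segment in coordinate space, not a geodesic; for the
synthetic planar scenarios any two endpoints may be supplied.

City-level cumulative case counts are broadcast unchanged to every
member cell of a city; the city→cell mapping is an input (in synthetic
scenarios, square blocks of cells).  This is the simplest reading of
"case counts at the city level" and is a stated assumption, not a
reconstruction of how any particular study downscaled cases.

## Land-use classification

Per-cell class counts are normalized by national class totals
(`F = n/N`) before forming percentage shares, so a class that is rare
nationwide can still dominate a cell.  The dominance rule is: label =
class *i* iff its share is the unique maximum **and** ≥ 50% (the
threshold is inclusive); otherwise mixed-use.  An exact two-way 50/50
tie is mixed because no *unique* dominant class exists.  Two residual
labels complete the partition: cells holding POIs of no classifiable
category are "other", cells with no POIs at all are
"non_human_activity"; both are excluded from change-rate summaries.
Sector classification of working (6 sectors) and entertainment (5
sectors) cells reuses the identical machinery over sub-category
national totals, with "mixed_sector" as the fallback.

Degenerate inputs are handled explicitly: a zero national total with a
positive cell count is an inconsistency and raises; zero with zero
yields F = 0 (logged).  Scale invariance (multiplying all counts and
totals by one constant) and dominance monotonicity (growing the
winner's count never dethrones it) are enforced by property tests.

## Change rates

Each observation day contributes 48 half-hourly bins; a bin belongs to
a class window when its *start* time lies in the half-open clock
interval, making the residential/working/entertainment/mixed windows
exactly 4/16/10/30 bins.  Period rates compare each later day with the
common baseline day; a zero baseline window sum makes all three rates
undefined for that cell.  Undefined cells are excluded *pairwise per
period* with counts reported, rather than dropping the cell globally —
zero baselines are a property of one window sum, not of the cell.
Summaries (per class, per sector, negative-change shares, east/west)
are unweighted means over cells; an intensity-weighted mean would
over-represent dense cells, and with no stated convention to follow,
the cell-weighted mean is the documented choice.

## Regression forest and MDG importance

The forest is bagged CART: each tree grows greedily on a bootstrap
sample, scanning every candidate (variable, threshold) pair — with
thresholds at midpoints between consecutive sorted unique values — for
the split maximizing the decrease in summed squared deviation from
node means.  Ties break toward the lowest variable index, then the
lowest threshold, so fits are bit-reproducible under a seed.  Defaults:
100 trees, bootstrap on, all 8 features considered at every split
(feature subsampling adds little with p = 8), `min_samples_leaf = 5`,
unlimited depth.  Splits with relative impurity decrease below 1e-12
are rejected to keep the bookkeeping identity (root impurity − leaf
impurities = summed importances) exact against floating-point noise.

MDG importance sums each variable's impurity decreases over all splits
in the forest, divides by tree count, and is reported as normalized
shares (summing to 1) because relative importance is the quantity of
interest; raw MDG values are retained alongside.  Importance is
computed on the training partition of the 55/30/15 split; metrics are
reported for train and test, with the validation slice reserved for
hyperparameter sanity checks.  Remainder indices from rounding the
fractions go to the training set.  Categorical attributes (urban/rural
binary, ordinal administrative level) enter the trees as ordered
integers and GWR as integer covariates — a known limitation: the trees
can only cut them at ordered thresholds.

Mean-decrease-accuracy (permutation) importance is deliberately not a
headline output; the scikit-learn forest serves as an independent
direction check in the test suite only.

## Geographically weighted regression

At each calibration location a weighted least-squares system is solved
with Gaussian kernel weights `exp(−d²/(2h²))`.  Bandwidth `h` is either
fixed or chosen by leave-one-out CV over a logarithmic grid spanning
the 5th percentile to the maximum of pairwise distances.  A bandwidth
that leaves any location with fewer than p + 1 effectively weighted
neighbours raises with guidance rather than returning a rank-deficient
fit; genuinely singular local systems (e.g. locally constant
covariates) are resolved by a trace-scaled ridge jitter and logged.
Out-of-sample predictions use the nearest calibration location's
coefficients.  As h → ∞ the local fits provably collapse to global
OLS, which the tests verify to 1e-6.

## Synthetic scenario generator

The generator emulates the *statistical shape* of the study inputs,
not any real geography:

- **Labels.** Cells draw a planted label from a configurable mix whose
  default (residential 16%, working 54%, entertainment 12%, mixed 18%)
  mirrors the relative class abundances reported for China-wide grids,
  making residential POIs the nationally rarest class.
- **POIs.** Each cell receives a Poisson(120)-sized multinomial draw
  over the 13 first-level categories.  Because the classifier
  normalizes by national totals that are themselves sums of the draws,
  a pure cell's raw draw probabilities must be calibrated: the
  generator solves for per-label class mixtures such that the planted
  class's *expected normalized share* equals the dominance parameter
  (default 0.7), with mixed cells drawing at the national composition
  (which pins their expected shares at exactly 1/3).  The remaining
  freedom is resolved by maximizing the balance (∑ log ρ) of the
  national composition: naive fixed-point targeting of all three
  shares collapses ρ toward a single class, and the resulting
  near-zero expected counts for rare classes would destroy label
  recovery through sampling noise alone.  The calibration is a
  deterministic SLSQP solve, so scenarios remain bit-reproducible.
- **Attributes.** Continuous fields (GDP, population density, built-up
  area, bus-stop and junction densities) are spatially smooth
  lognormal-type surfaces built from Gaussian-filtered noise;
  urban/rural thresholds population at its 70th percentile;
  administrative level is a GDP quartile (1–4); cumulative cases are a
  city-block-level lognormal draw broadcast to member cells.
- **Planted change rates** are a linear — hence monotone — function of
  standardized attributes.  Skewed positive attributes enter through
  `log(1+x)` (still monotone in the raw attribute) so the link has
  Gaussian rather than lognormal tails; raw-scale standardization
  produced occasional planted rates below −100%, which the intensity
  generator rightly rejects.  Default effects center the three periods
  near −25%, −8% and −6.5% with GDP the strongest driver and junction
  density second, matching the magnitudes the method is meant to
  detect.
- **Intensity.** Day 1 is a fixed smooth two-peak diurnal curve scaled
  by a per-cell amplitude; only window sums matter downstream, so the
  curve's exact shape is irrelevant to correctness.  Later days copy
  day 1 and scale the bins inside the cell's class window by
  `1 + (rate + ε)/100`.  The noise ε is **uniform** with standard
  deviation `noise_sd` (half-width `noise_sd·√3`): a bounded
  perturbation guarantees nonnegative scale factors — hence nonnegative
  intensities — for any planted rate above −100% plus the noise bound,
  which an unbounded Gaussian cannot.  Noise applies to the window
  scale factor, not per bin, so at `noise_sd = 0` realized rates invert
  the planted rates exactly (to float round-off).
- **RNG discipline.** Each stage owns an independent stream seeded
  `seed + fixed offset`, so any stage can be regenerated in isolation
  and whole scenarios are bit-identical under one seed.

What passing tests on this generator do **not** show: robustness to
the measurement quirks of real LBS counts (device mix, request-rate
artifacts, day-of-week effects), to POI misregistration or taxonomy
drift, or to attribute rasters whose errors correlate with the
outcome.  The generator's attribute→change link is also far cleaner
than any real dependency; importance recovery on synthetic data is a
correctness check of the MDG computation, not evidence about real
effect sizes.

## Problem sizes and numerical choices

Tests and the acceptance script use grids of 100–1,000 cells, forests
of up to 100 trees and GWR fits on a few hundred locations — sizes at
which every check runs comfortably on a single CPU while still
exercising the estimators beyond toy regimes.  Tolerances: exact
arithmetic identities are asserted to 1e-12, round-trips through the
generator to 1e-9, the GWR flat-kernel limit to 1e-6, and stochastic
recovery properties at the rates stated in their tests (e.g. planted
pure-label recovery ≥ 95% at dominance 0.6).

The pipeline writes every stage as tidy CSV keyed by `cell_id` and
records a JSON manifest of config hash, seed and per-file SHA-256
digests; wall-clock timings go to a separate log so manifests are
comparable across runs.  A rerun reuses any stage whose outputs match
the recorded digests and rebuilds exactly the stages whose files are
missing or modified.

## Known limitations

- Coordinates are treated as planar throughout; there is no projection
  engine, and lon/lat inputs are handled as if Euclidean.
- The GWR uses one global bandwidth and a Gaussian kernel only;
  adaptive (k-nearest) kernels are not implemented.
- Sector-level planting in the generator is approximate: the
  within-class calibration assumes sectors are planted uniformly, so
  sector recovery is looser than class recovery.
- `change_table` holds all intensity days in memory; grids far beyond
  ~10⁵ cells would need chunked processing.
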