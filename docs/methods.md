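# Methods

## Model and assumptions

The pipeline treats grazing capacity as a pure function of forage supply.
Annual net primary productivity (NPP, g C m⁻² yr⁻¹) is split into its
aboveground fraction with a linear function of mean annual temperature
(f_ANPP = 0.171 + 0.0129·MAT), converted from carbon to dry matter by
dividing by the biomass carbon fraction, and reduced by two geographic
restrictions: an exponential canopy-shading multiplier exp(−4.45521·x) on
the tree-cover fraction x, and a step-function slope multiplier encoding
that steep terrain is grazed less to avoid erosion. Carrying capacity
divides the annual forage supply by the annual requirement of one animal
unit (455 kg body weight × daily intake fraction × 365 days). Relative
stocking density divides the reported animal-unit density by that capacity
and is classified against the minimum (0.20) and maximum (0.65) proper-use
factors found in the rangeland literature.

Implicit assumptions worth keeping in mind: forage limitation is the only
constraint (no water, disease, herd mobility or supplementary feed); all
grass-bearing classes (IGBP woody savannas, savannas, grasslands) are
treated alike; the linear partitioning model is extrapolated everywhere it
is positive and simply truncated (cells excluded) where it is not, i.e.
below its root at −0.171/0.0129 ≈ −13.26 °C. The exclusion is applied at
the exact root rather than a rounded integer degree: the equation, not its
rounding, defines the domain.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| f_ANPP intercept / slope | 0.171 / 0.0129 | – / °C⁻¹ | grassland NPP-partitioning regression |
| carbon fraction | 0.475 | g C (g DM)⁻¹ | conventional biomass carbon fraction, inside the sampled [0.47, 0.50] |
| canopy decay | 4.45521 | – | fit of understory production against canopy cover; 1 at x=0, ≈0.012 at x=1 |
| slope classes | ≤10 %→1.0, ≤30 %→0.7, ≤60 %→0.4, else 0 | – | standard rangeland utilisation recommendation; bounds inclusive downward |
| AU weight | 455 | kg | reference grazer definition |
| daily intake | 0.02 of body weight | – | point value inside the plausible 0.018–0.04 |
| AU factors | cattle 1.0, buffalo 0.65, sheep/goat 0.125, horse 1.1 | AU head⁻¹ | stated means or interval midpoints |
| RSD thresholds | 0.20 / 0.65 | – | min/max proper-use factors; both boundaries classify as "medium" (closed-interval reading) |
| AGB display floor | 0.1 | g m⁻² yr⁻¹ | maps are masked to cells with non-negligible forage; applied to outputs, never inside the arithmetic |
| trend α | 0.05 | – | per-pixel significance mask; zonal Kendall trends starred at 10/5/1 % |

Every value is overridable through the YAML run configuration.

Degenerate cells: capacity zero with stock present yields RSD = +inf and
classifies as overstocked (any stock on zero forage exceeds capacity);
capacity zero with zero stock is nodata — there is nothing to judge.

## Uncertainty propagation

The uncertain scalars (intake, carbon fraction, five species AU factors,
and multiplicative product errors on NPP and f_ANPP) are sampled
independently — truncated normals inside their stated bounds, uniforms for
the (mean, sd) rows with support mean ± √3·sd — and each draw reruns the
deterministic AGB → CC → RSD chain with the sampled scalars applied
globally. Sampling globally rather than per pixel is deliberate: these are
conversion constants, and independent per-pixel perturbations would
average out and understate map-level uncertainty. Ensembles are summarised
per pixel by the median and the CV (100·sd/mean, sample sd with n−1).
Parameter streams are keyed by (seed, parameter name), so adding a
parameter never shifts another's draws.

Two defaulting rules fill in distribution rows that state bounds only:
mean = midpoint and sd = range/4 (≈95 % of untruncated mass inside the
bounds). Rows that state a mean but no sd take sd = (distance to the
nearer bound)/2 — this yields the cattle sd of 0.125 and an intake sd of
0.001, keeping the sampled intake mean at ≈0.02 where the range/4 rule
would let the asymmetric truncation drift it to ≈0.023. The canopy-decay
coefficient itself is not sampled: its published uncertainty is a
percentile band around a fitted curve, not a scalar interval, and is left
out of the propagated set (a known limitation). With the default set, the
CC coefficient of variation is ≈16 % everywhere (the sampled scalars act
multiplicatively, so the CV is pixel-independent), consistent with the
delta-method prediction CV²(CC) ≈ Σ CV²(parameters), which the test suite
checks at n = 1000 within 15 % relative tolerance.

"Monte Carlo" here is forward error propagation; nothing is conditioned on
data, so there is no Markov chain or posterior.

## Temporal statistics

Per-pixel trends are closed-form OLS of the annual value on the 0-based
year index (slope = Σ(t−t̄)(y−ȳ)/Σ(t−t̄)², two-sided t-test), requiring at
least three valid years; the mapped change is slope × number of study
years, masked to significant pixels. No multiple-testing correction is
applied across pixels — each pixel is presented on its own, which inflates
the family-wise error of "significant area" fractions; treat those areas
as descriptive. Zonal annual series (any integer-coded zone raster; sum,
mean, median or area per year) get a Kendall tau-b trend with 10/5/1 %
stars. Interannual variability is the CV across years (nodata where the
mean is non-positive) and the minimum-to-median ratio summarises how bad
the worst year is relative to a typical one.

## Synthetic worlds

The generator builds all seven input layers on one geometry from a single
seed. NPP follows base(x,y)·(1+β(x,y)·t)·ε with ε lognormal(0, σ²) i.i.d.
per pixel and year — multiplicative noise keeps NPP positive and
right-skewed, matching CV-style variability measures. Spatial structure is
separable moving-average smoothing of white noise; temperature combines a
latitudinal gradient, a coupling to the NPP base anomaly, and smooth
noise. Land cover is a mosaic with an *exactly* configured grassland
fraction (denser canopy maps to woodier classes), plus per-year spurious
class flips capped below half the years so the modal composite provably
recovers the base map. Livestock is constructed backwards: each usable
pixel draws a target RSD inside one of the three classes (kept clear of
the 0.20/0.65 boundaries so rounding cannot flip a label), multiplies by
the point-parameter capacity, and splits into species headcounts with
gamma-weighted shares — making the classification ground truth and the
implied AU density exact test oracles.

Defaults represent the study conditions: 15 years, σ = 0.1 interannual
noise, trend field β with sd 0.01 yr⁻¹ around zero, 70 % grassland, class
mix 42/28/30 % low/medium/overstocked, a 5-year stocking window in the
middle of the period, and a 60 % livestock-grazing system extent. What the
generator does **not** emulate: real geographic pattern, sensor artifacts,
spatially correlated noise across years, co-varying parameter errors, or
headcounts inconsistent with the capacity model. Passing tests therefore
demonstrate the correctness of the computation and the recoverability of
planted signal at realistic noise — not the accuracy of the model on real
rangelands.

## Numerical choices

- Nodata is NaN internally for continuous layers (sentinel only on disk);
  integer layers carry an in-band sentinel. NaN propagates through all
  arithmetic; +inf is reserved for infinite stocking pressure.
- Land-cover mode ties break to the smallest class code (deterministic).
- Continuous resampling is the exact separable area-weighted mean with
  nodata excluded from the average; categorical resampling is nearest
  neighbour at cell centres. Only affine-aligned grids in a shared CRS are
  supported; reprojection is out of scope.
- Canopy anchors are interpolated linearly per year (exact at anchors,
  nearest-anchor extension outside the range) *after* the non-linear
  canopy transfer would be applied at native resolution — order matters
  because the transfer is non-linear.
- A perfect noiseless linear fit gets p = 0 (significant) unless the
  series is constant, in which case slope 0, p = 1.
- Problem sizes: the reference suite uses 48×48–64×64 grids over 15 years
  and 1000 Monte-Carlo draws, which keeps every check comfortably
  desk-scale while leaving ≥1000 grassland pixels for distributional
  assertions.

## Known limitations

Single annual time step (no seasonality or within-year feed gaps); no
supplementary feeding, herd movement, or species-specific forage quality;
canopy-curve uncertainty not propagated; per-pixel trend significance
uncorrected for multiple testing; no CRS reprojection. The ESRI
ASCII/NetCDF I/O pair favours transparent, text-first interchange over
compressed binary formats.
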