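# Methods

## Data model and conventions

A saccade is a pair (θ, r): direction θ in degrees in [0, 360), measured
against the horizontal screen axis, and amplitude r ≥ 0 in degrees of
visual angle or screen pixels. Screen coordinates have their origin at the
top-left with y increasing downward; directions are therefore computed from
displacement vectors *after inverting screen-y*, counter-clockwise
positive, so 90° means "up the screen" and polar plots read like
mathematical diagrams. Eye-tracker exports that use the clockwise screen
convention are handled by a `clockwise` flag in `derive_saccades` and the
plotting functions, not by silently reinterpreting angles.

Amplitude units never mix within a table; conversion between degrees of
visual angle and pixels goes through a pixels-per-degree (ppd) factor. When
a known factor exists (e.g. a vendor-reported value such as 39.04 px/deg)
it is used verbatim via `ppd_override`; otherwise ppd is derived as the mean
horizontal factor over the full screen subtense,
`width_px / (2·atan(width_mm / 2d) in degrees)`. The two differ for
off-axis pixels; the mean-subtense form was chosen because it needs no
assumption about where on the screen a saccade lands.

AOI (area-of-interest) filtering keeps a saccade iff its start point lies in
some AOI *and* its end point lies in some AOI — "within" one AOI or
"between" two. Rectangles are half-open, `[x, x+w) × [y, y+h)`, so a point
on a shared edge belongs to exactly one AOI and membership is
deterministic.

## Direction density: von Mises kernel

The circular KDE is the direct summation
f̂(θ) = (1/n) Σᵢ vM(θ; θᵢ, ν), with the von Mises kernel
vM(θ; μ, ν) = exp(ν·cos(θ−μ)) / (2π·I₀(ν)). The concentration ν acts as an
inverse squared bandwidth (kernel circular sd ≈ 1/√ν radians); ν = 0 is the
circular uniform. Densities are always per radian, so the uniform density
is 1/(2π) regardless of grid units. Numerically the kernel is evaluated as
exp(ν·(cos Δ − 1)) / (2π·i0e(ν)) with the exponentially scaled Bessel
function, which is stable for arbitrarily large ν (no overflow above
ν ≈ 700, where the naive form fails).

The default ν comes from a Taylor-type plug-in rule assuming a von Mises
reference density:

ν = [3·n·κ̂²·I₂(2κ̂) / (4·√π·I₀(κ̂)²)]^(2/5),

with κ̂ obtained by inverting A(κ) = I₁(κ)/I₀(κ) = R̄ (bracketed Brent root
finding, tolerance 1e-10, capped at 10⁶ as R̄ → 1). ν grows as n^(2/5)
(kernels sharpen with more data) and collapses to 0 (maximal smoothing) for
near-uniform samples. The rule assumes unimodality: on strongly clustered
or multimodal direction data it over- or under-smooths, which is why every
estimator accepts an explicit ν and analyses meant to be compared should
pin it in their configuration.

The Gaussian-linear baseline treats θ as an unbounded linear variable — no
wrap-around — deliberately reproducing the legacy boundary artifact: mass
contributed by samples near 360° never reaches grid points near 0°. Its
bandwidth is specified in degrees; where a comparison against the von Mises
estimate is wanted, `matched_gaussian_bandwidth_deg` equates the kernels'
circular variance (σ = √(−2·ln A(ν))), so differences between the two
estimates reflect the wrapping, not unequal smoothing.

## Joint density: mixed product kernel on a polar grid

The mixed estimator is the product kernel
f̂(θ, r) = (1/n) Σᵢ vM(θ; θᵢ, ν)·G_refl(r; rᵢ, h), where
G_refl(r; rᵢ, h) = N(r; rᵢ, h) + N(r; −rᵢ, h) reflects each radial Gaussian
at r = 0. Reflection rather than truncation keeps each kernel's full mass
on [0, ∞) without a renormalization bias near zero. The grid is uniform in
both coordinates — by default 1° angular step, 200 radial steps up to
r_max = 1.05 × the largest observed amplitude (a recorded truncation
warning is attached if r_max cuts the 99th amplitude percentile). Under the
default `polar_area` normalization the grid is rescaled so the polar
Riemann sum Σ f̂·r·Δr·Δθ equals 1: the estimate is a proper joint density
over the plane, comparable across datasets and independent of sample size.
The raw product values are retained under `coordinate_area` for verification
against direct summation. The Gaussian-only baseline swaps the von Mises
factor for a linear no-wrap Gaussian and shares the grid and normalization,
so the two estimates differ only in the directional kernel.

Default joint bandwidths rescale the univariate rules to the bivariate
smoothing rate. The 1-D plug-in ν and Silverman's amplitude rule
h = 0.9·min(sd, IQR/1.34)·n^(−1/5) both target the univariate MISE-optimal
bandwidth rate n^(−1/5); for a two-dimensional product kernel the optimal
per-axis rate is n^(−1/(d+4)) = n^(−1/6). `joint_bandwidths` therefore
multiplies ν by n^(−1/15) and h by n^(1/30). Without this adjustment the
joint estimate is visibly under-smoothed and its grid mode wanders several
degrees around the true mode on samples of a few thousand saccades.

## Probability grids and the normalized divergence

For comparison, a density grid becomes a discrete probability distribution:
cell (j, k) gets mass ∝ f̂(θⱼ, rₖ)·rₖ·Δr·Δθ, renormalized to sum exactly 1
(the r = 0 ring carries no mass — its area element vanishes). The
Jensen–Shannon divergence between two such grids uses base-2 logarithms, so
it lies in [0, 1] and reads directly as a fraction of the maximal possible
divergence; a `log_base` parameter exposes the natural-log variant (bounded
by ln 2). Zero-mass cells follow the 0·log 0 ≡ 0 convention with no
epsilon flooring, which would bias small divergences upward. Because both
inputs are normalized to unit mass, group sizes never enter a between-group
divergence.

## Synthetic generator

The generator emulates AOI-filtered saccades from a two-alternative
selection task: directions from a mixture of von Mises components,
amplitudes from Gamma laws (right-skewed, strictly positive), endpoints
placed uniformly so each displacement fits a 1920×1080 screen. Two presets
encode opposite strategies:

| preset | direction mixture | amplitude |
|---|---|---|
| `correct_like` | 0.45·vM(0°, 12) + 0.45·vM(180°, 12) + 0.10·vM(90°, 4) | Gamma(4, 25 px) |
| `incorrect_like` | vM(90°, 0.5) (nearly flat) | Gamma(4, 60 px) |

`correct_like` mimics targeted horizontal comparison scanning with short
saccades; `incorrect_like` mimics diffuse exploratory search with saccades
~2.4× longer on average. The parameter values are package conventions
chosen to produce those qualitative contrasts at realistic screen scales;
they are not fitted to any empirical dataset. Each table is drawn from one
seeded generator consuming, per saccade, in order: component index,
direction, amplitude (redrawn until the displacement fits on screen), start
point — so (scenario, n, seed) pins the table exactly.

What the generator does *not* emulate: temporal structure (no fixation
durations, no scanpath sequencing), measurement noise and event-detection
errors, participant heterogeneity (draws are i.i.d., not nested), or
AOI-geometry-induced direction/amplitude correlation beyond what the
mixture encodes. Tests passing on this generator certify the estimators'
mathematical behavior, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Angles are reduced modulo 360 with a guard so values like −1e−15 never
  emerge as 360.0.
- The circular mean is flagged undefined (`mean_deg = None`) when the
  resultant length is below 1e−12 (e.g. antipodal data) — never silently 0°.
- KDE evaluation is exact direct summation (the estimator's definition);
  grids of 360×200 over thousands of saccades are a single matrix product,
  so no FFT approximation is warranted at this scale.
- CSV grid exports use 17-significant-digit formatting and are re-read with
  round-trip float parsing, so save → load → compare is bit-exact.
- Unparseable table rows are skipped with a logged tally; above 50 % skipped
  the column mapping is presumed wrong and reading aborts.
- Endpoint/amplitude consistency is enforced to 0.5 px whenever a conversion
  factor makes it checkable.

## Problem sizes

The test and reproduction workloads use n between 50 (brute-force oracle
comparisons) and 10⁴ (mixture-weight convergence), with n = 1000–2000 for
recovery and group-contrast checks — comparable to the number of
AOI-filtered saccades a task-based eye-tracking session of a few dozen
participants yields per group.

## Known limitations

- The von Mises kernel, like its Gaussian analogue, assumes local
  unimodality; heavily multimodal direction patterns can be over-smoothed,
  and the plug-in ν is unreliable there (pin ν explicitly).
- The divergence is descriptive: no permutation test or other significance
  machinery is attached to a JSD value.
- Saccade velocity is outside the data model; only direction and amplitude
  are represented.
- Event detection is out of scope: the package starts from detected
  fixations or exported saccade tables, not raw gaze samples.
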