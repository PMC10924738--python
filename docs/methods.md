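# Methods

This note documents the models, the synthetic-trial generator, the
numerical choices, and the known limits of what the test suite
demonstrates.

## Daily-growth reaction norms

The central object is the genotype- and stage-specific reaction norm of
daily growth to soil moisture.  For plot `i` on day `d` (integer days
after sowing, DAS),

    Δy_{i,d} = y_{i,d} − y_{i,d−1} = SP_{i,d}(s_{i,d−1}) + e_{i,d},
    SP_{i,d}(s) = Σ_{q=1..Q} c_{q,i,d} φ_q(s),

where φ is a B-spline basis over the observed soil-moisture support and
`Q ∈ {3, 4, 5}`.  Using *growth* as the response (not the trait level)
encodes the persistence of stress effects: a plant stunted by a dry spell
does not bounce back when the water returns, it just resumes growing from
a smaller size.

The coefficients are assumed to vary smoothly over genotypes and days.
Rather than a mixed model, each target (genotype `i`, day `d`) is fit by
locally weighted least squares (a varying-coefficient model): record
`(i', d')` receives weight

    w = max(G_{i,i'}, 0) · k₀(d − d'),   k₀(x) = exp(−x²/λ₀),

with `G` a genomic relationship matrix (negative entries zeroed when used
as weights) and `λ₀ ∈ {10, 30, 50, 70}`.  The solve is closed-form
(normal equations) and vectorised across all targets by exploiting the
separable weight structure; plots of the same genotype share a target
because the weights depend only on (genotype, day).  Replicate plots of a
genotype in other environments enter with full genomic weight — their
different moisture histories are what identify the curve.

### B-spline basis

Clamped cubic basis with exactly Q functions: boundary knots at the
observed moisture min/max, `Q − degree − 1` interior knots at equally
spaced quantiles of the moisture sample, degree reduced to `Q − 1` when
`Q ≤ 3`.  The basis is a partition of unity on its support.  Evaluation
outside the support clamps the argument to the boundary — spline
extrapolation at the periphery of the observed moisture range is known to
be unstable, and a clamped constant continuation is the most conservative
choice.  Curve exports carry an `in_support` mask (moisture observed
within ±5 days of the probe day) so users can shade unsupported regions.

### Numerical safeguards

- Per-target ridge `ε = ridge · (Σw) · var(Δy)` with `ridge = 1e-6` by
  default; `ridge = 0` recovers plain WLS and is what the oracle tests
  use on well-conditioned fixtures.
- A target genotype with no positive kernel entry against any training
  genotype would have zero total weight; such targets fall back to
  uniform weights (the population-average reaction norm) and are recorded
  in `uniform_fallback_`.  This matters only for very small panels.

## Random-forest growth model

`y_{i,d} = RF(y_{i,d−1}, g_i, s_{i,d−1}, d)`: the response is the trait
*level* and the previous-day level is a predictor, deliberately asymmetric
to the spline model — it lets the forest discover size-dependent growth.
`g_i` is the genotype's kernel column restricted to training genotypes
(the only definition that extends to unseen genotypes).  Defaults:
500 trees, `mtry ∈ {5, 10, 15, 20, 25, 30}` (values exceeding the
predictor width are reduced), fixed seed.  Forest predictions are bounded
by the training response range, which also bounds the sequential
recursion.

## Supporting stages

**Height bias.**  Remote-sensed canopy height has a day-specific
multiplicative bias vs manually measured plant height.  Per day,
`b_d = Σ PH·CH / Σ PH²` (through-origin least squares over ground-truth
plots); days without ground truth get linearly interpolated `b_d`
(boundary days carry the nearest estimate); series are corrected as
`CH/b_d` *before* smoothing.

**Smoothing splines.**  Cubic smoothing spline minimising
`Σ(obs − f)² + λ ∫ f″²` (scipy's `make_smoothing_spline`), evaluated on
the integer-day grid.  Default penalties 1e-4 (canopy area) and 1e-3
(height).  Penalty parameterisations differ across spline
implementations; the defaults here are defined on the objective above and
equivalence to any other ecosystem's `lambda` is not claimed.

**Soil-moisture interpolation.**  Within each row (one watering tube, so
rows are treated as independent), target (position l, day d) is the
kernel-weighted mean of measurements with weights
`exp(−(l−l')²/λ_s) · exp(−(d−d')²/λ_t)`; positions are integer plot
indices.  Every interpolated value is a convex combination of same-row
measurements and therefore bounded by their range.  Bandwidths are chosen
jointly over a 17×17 log-spaced grid on [0.1, 1000] by leave-one-out RMSE
(single-point exclusion); ties break toward the smaller pair,
lexicographically, preferring locality.  Rows without measurements error
by default, or (opt-in) are filled with the mean of the nearest measured
rows.

**Genomic kernels.**  Scores −1/0/1; markers filtered at MAF ≥ 0.025,
missing rate < 0.05, then greedily LD-pruned at r² ≥ 0.95 within a
50-marker window.  Linear kernel `Xc Xc' / (2 Σ p(1−p))` (VanRaden);
Gaussian kernel `exp(−‖x_i−x_j‖²/λ_g)` on centred rows with λ_g = 1e5 by
default (an optional CV routine over 1e5–1e7 is provided).  Missing
scores must be imputed first; only per-marker mean imputation is offered,
with a warning — dedicated imputation software should be used for real
data.

**GBLUP baselines.**  `y = Xβ + Zu + e`, `u ~ N(0, σ_g² K)`.  REML
profiles the likelihood over `λ = σ_g²/σ_e²` with bounded scalar
optimisation on the log scale (robust for a single variance ratio);
BLUPs, including unobserved genotypes via kernel cross-covariance, come
from the closed-form mixed-model equations.  The scheme dictates the
structure: CV-G fits one kernel model per environment; CV-E one
all-environment model with fixed environment effects and an *identity*
genotype covariance (test genotypes are observed in other environments);
CV-GE the all-environment model with the kernel.  An environment never
seen in training takes the mean of the training environment effects as
its fixed part.  GP fits each day's level; GPG fits each day's increment
and accumulates from the first-day prediction (so its trajectory minus
the first-day prediction is exactly the cumulative sum of predicted
increments).

## Synthetic trials

The generator emulates a drought phenotyping trial end to end and is the
oracle for every downstream test.

- **Genotypes.**  Biallelic SNPs under Hardy–Weinberg with per-marker MAF
  uniform on [0.025, 0.5]; markers whose empirical MAF falls below the
  floor are redrawn, so simulated panels pass the standard MAF filter.
  Markers are unlinked.
- **Soil moisture.**  Deterministic treatment means by first-order
  relaxation toward a watered set-point (6 %v/v) or a dry floor (2 %v/v)
  — rates 0.8 (rise) and 0.25 (decay) per day — with watering always on
  (WW), never (W0), or cyclic 5-on/5-off (W5) / 10-on/10-off (W10); the
  cyclic series reach their periodic cycle to float precision after about
  two cycles.  Set-points are configurable, not claims about any real
  field.  Along-row correlated Gaussian noise (squared-exponential over
  position) is added per day.
- **True reaction norms.**  `c_{q,i,d} = μ_q(d) + genetic + shared
  environmental deviation`.  μ has amplitudes increasing in q (growth
  increases with moisture) and a mid-season bump over days.  The genetic
  part is built from random marker effects smoothed over days by a
  squared-exponential day kernel, so its genotype covariance is
  proportional to the linear genomic kernel and clones get identical
  curves; the non-genetic part is one smooth day curve shared by all
  genotypes.  `h2_coef` splits the variance (default 0.8).  Optionally,
  k discrete drought-response classes are planted as offsets (±1 cm/day
  between adjacent classes) on the lowest-moisture basis coefficient,
  assigned by k-tiles of a marker-based latent score — classes are
  genetically determined, matching the premise that genotype differences
  are genomic.
- **Growth and observation.**  Realised daily growth is the spline value
  plus Gaussian noise (default SD 0.1 cm/day), floored at zero (plants do
  not shrink); the unclipped cumulative trajectory is also stored, since
  it is what the unfloored growth recursion reproduces exactly.  Initial
  size is log-normal (median 5 cm, CV 0.3) with a heritable early-vigour
  component (h² = 0.7) — diversity panels vary widely and heritably in
  early vigour, and without it the first observation day would carry no
  genetic signal at all.  Observed heights are `b_d · y + noise` with
  daily bias uniform on [0.8, 1.2]; manual ground truth (bias-free) is
  recorded on a few reference plots per environment; soil moisture is
  observed on every third plot position, in two groups measured on
  alternating days.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: growth does *not* depend on current plant size
(the spline model is exactly correctly specified, so its advantage here is
by construction); there is no phenology drift, no weather input other
than soil moisture, no marker linkage disequilibrium, no heteroscedastic
or outlier-prone measurement error, and no image-level artefacts.  One
consequence is visible in the CV profiles: on real data the sequential
spline model's accuracy has been observed to *fall* along the season as
recursion errors compound, while on these synthetic trials genetic signal
accumulates faster than error and per-day accuracy of both sequential
models rises along the season.  The error-accumulation mechanism itself
is real and is verified directly: an error injected into the first day's
prediction propagates undiminished through the whole spline recursion.

## Cross-validation protocol

CV-G: 5 genotype folds × 10 repeats (reducible; the canned directional
experiment uses 2), within every environment.  CV-E:
leave-one-environment-out.  CV-GE: every (fold × environment) cell,
training on the other folds × other environments only.  Integrity —
disjoint plots, and no shared genotype (CV-G/GE) or environment
(CV-E/GE) between training and test — is asserted on every cell of every
run.  Accuracy is Pearson r per (environment, day) across test plots,
averaged over repeats before any model comparison; zero-variance cells
are excluded and logged, and model-vs-model win counts use strict
inequality with ties reported separately.

## Problem sizes

Validation experiments run at desk scale, chosen so the full suite and
the acceptance script each finish in minutes on one CPU: 40 genotypes ×
400 markers × 4 treatments × 50 days for recovery and directional
experiments (2 CV repeats), 8–12 genotypes for exactness and determinism
checks.  Recovery rates are seed-dependent at this scale (the fraction of
targets with curve correlation > 0.9 moves a few points across seeds),
and the per-day CV accuracy summaries are noisy: with 2 repeats, 5 folds
and 8 test plots per cell, early/late season contrasts can change sign
between seeds.  Conclusions about accuracy trends should be drawn from
full-size runs (10 repeats, larger panels), not from the desk-scale
numbers.

## Determinism

All randomness flows from explicit seeds (`SimConfig.seed`, forest seed,
CV-plan seed); reruns with the same configuration are bitwise identical,
which the suite asserts on whole-pipeline CSV/JSON output.
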