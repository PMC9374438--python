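# Methods

`plumeloc` studies a question from olfactory sensory ecology: which summary
statistics of a short, turbulent odor signal best predict how far away the
odor source is? The package implements the full inference pipeline —
signal features, supervised regression, and a Bayesian account of the best
achievable error — and a synthetic plume generator that provides study
conditions with known ground truth.

## The signal model

Odor downwind of a concentrated source arrives in *whiffs* (excursions
above a detection threshold) separated by *blanks*. The synthetic
generator reproduces this intermittency with the simplest process that
lets intensity and sparsity be tuned independently: each grid cell inside
an emission cone carries an alternating-renewal (telegraph) process,

- blank durations ~ Exponential(mean `tau_b(r)`),
- whiff durations ~ Exponential(mean `tau_w(r)`),
- per-whiff amplitude `C(r) * xi`, `xi ~ LogNormal(0, sigma_ln)`,
  constant within the whiff,

with `r` the distance from the source, envelope
`C(r) = c0 (max(r, r_min)/r_min)^(-alpha) / (1 + h)` and duration laws
`tau(r) = tau0 (max(r, r_min)/r_min)^e`. The `height_factor` `h` scales
blank durations up and the envelope down, emulating sampling planes
further from the substrate, where odor is sparser and weaker. Durations
are drawn in continuous time and rounded **up** to whole samples, so the
binary state is well defined at the sampling rate; the realized mean
duration of a draw with nominal mean `tau` is therefore
`dt / (1 - exp(-dt/tau))` (a geometric count), and all ground-truth laws
use this discretized form. Time is measured in sampling intervals — one
snapshot per Kolmogorov time by convention — and lengths in grid cells.
Cells outside the geometric cone are exactly zero; the model makes no
claim about that region.

What the generator deliberately does **not** reproduce: spatial and
temporal correlations between cells (each cell is independent),
non-exponential duration tails, within-whiff concentration dynamics
(whiffs are flat unless the optional ramp is enabled), crosswind asymmetry
and meandering of real plumes. Passing tests on this generator therefore
demonstrate that the *pipeline* behaves as documented under controlled
renewal statistics, not that any particular feature ranking holds in a
specific real flow.

### Study-condition presets

Two presets bracket the conditions of interest. Their parameters were
fixed from a renewal signal/noise analysis of the generator itself (how
much each feature's window average varies across the cone, relative to
its within-window sampling noise), not fitted to any measured flow:

- **concentrated** (near-substrate analog): `alpha = 1.5`,
  `sigma_ln = 0.3`, `tau_w = 8`, `tau_b = 12 r^-0.35`. The intensity
  envelope spans more than two decades across the cone, so intensity
  features dominate; the duty cycle rises mildly downwind (the signal is
  most intermittent near the source), so timing features carry weak but
  real signal.
- **dilute** (elevated-plane analog): `alpha = 0.05`, `sigma_ln = 0.5`,
  `tau_w = 6`, `tau_b = 9 r^-1`, `r_min = 6` cells. Intensity barely
  depends on distance and fluctuates strongly, while blank durations fall
  by an order of magnitude across the cone; blank duration and
  intermittency factor dominate.

Beyond the two presets, the experiment layer sweeps the `height_factor`
(ranking as a function of mean intermittency, the elevated-plane analog)
and splits the cone at a configurable distance into proximal and distal
sub-problems that are trained and scored separately.

Two non-obvious constraints shaped these choices. First, window-level
estimates of timing features only carry signal if a window spans many
renewal cycles; duty-cycle gradients built from whiff durations comparable
to the window length are invisible. Second, a power law relative to a
one-cell `r_min` concentrates its variation in the first few cells,
whereas the triangular sampling prior puts most mass at large `r`; the
dilute preset therefore uses a larger `r_min` and a `-1` exponent, which
keeps the *relative* blank-duration gradient constant across the cone.

## Features

A series is binarized at the adaptive threshold
`cthr = 0.5 * mean(c | c > 0)` ("above" is strict, so zeros are
unambiguous blanks; exact ties are measure-zero for continuous signals).
Five features per series:

| | definition | class |
|---|---|---|
| `x1` | mean concentration over whiff samples | intensity |
| `x2` | mean over whiffs of the peak forward-difference slope | intensity |
| `x3` | mean blank duration (0 if no blank) | timing |
| `x4` | mean whiff duration | timing |
| `x5` | fraction of samples above threshold | timing |

Because the threshold is proportional to the signal, timing features are
exactly invariant under rescaling `c -> a c` and intensity features scale
linearly — the property that makes timing cues robust to unknown source
strength. Boundary-truncated runs count toward the duration averages
(dropping them would bias short series); durations are reported in time
units so results do not depend on the sampling convention. The per-whiff
peak slope includes the onset step from the sample preceding the whiff; a
length-1 whiff that starts the record has no defined step and is skipped
in the `x2` average. A series that never exceeds its threshold yields an
invalid (all-NaN) feature vector, never silent zeros.

## Cone of detection and datasets

The analysis region is the set of cells whose long-run detection
probability exceeds 0.35, where detection uses each cell's own adaptive
threshold over its full record — the same rule used everywhere else in
the pipeline. The cone length `R` is the largest downwind coordinate of
any such cell. Training and test examples are `M`-sample windows at
locations drawn uniformly (with replacement) over the cone; training
start times come from the first half of the record and test start times
from the second half, so the two sets never overlap in time. Windows
with no sample above threshold are redrawn, up to a 100x oversampling cap
(then the sampler fails loudly). The downwind output is the unsigned
coordinate `z1` with the source at the origin; crosswind uses signed
`z2`.

## Regression and the chi error

The estimator is kernel ridge regression with the Gaussian kernel
`k(x,x') = exp(-||x-x'||^2 / 2 sigma^2)` and closed-form coefficients
`c = (K + lambda N I)^{-1} y`, the minimizer of
`(1/N)||Kc - y||^2 + lambda c'Kc`. The solve is exact (dense Cholesky);
at desk scale no low-rank acceleration is needed, and with as many
inducing points as training points an accelerated solver would be
equivalent anyway. Features are standardized with training-split
center/scale before kernel evaluation so one width serves mixed-unit
subsets.

Hyperparameters are selected by 4-fold cross validation on a log-spaced
8x8 grid — `lambda` in `[1e-9, 1e1]`, `sigma` in `[1e-2, 1e2]` times the
median pairwise distance of the standardized inputs — refined by a 4x4
subgrid spanning one coarse step around the minimizer. Per fold and
width, the kernel matrix is eigendecomposed once so all `lambda` values
share the factorization. The search runs on a random subsample of the
training rows (default cap 1000) and the final solve uses the full
training set; the validation surface has a wide plateau around its
minimum, so the subsample locates it reliably while keeping the grid
search tractable.

Performance is the normalized test error
`chi = sum_i (y_i - f(x_i))^2 / sum_i (y_i - ybar)^2`. The constant mean
predictor scores exactly 1; predictions drawn i.i.d. from the empirical
output distribution (the package's random baseline) score 2 in
expectation, because each squared error then decomposes into the output
variance plus the point's own squared deviation. Reports carry per-point
squared errors normalized by the test-set mean squared deviation, whose
median and 95th percentile summarize the error distribution.

When feature pairs are compared with singles, note that pair estimation
converges more slowly in the training-set size; comparisons of best pair
versus best single are made at an `N` on the pair's plateau (the study
protocol's own reason for choosing a large training set).

## Expected-error model

For a scalar feature, the best possible predictor is the posterior mean
`f*(x) = E[y | x]` under the sampling prior and the feature's conditional
law. Uniform sampling over a cone of length `R` gives the triangular
prior `p(y) = 2y/R^2` (mean `2R/3`, variance `R^2/18`). Features are
window averages, so their conditional law is modeled as Gaussian,
`p(x|y) = N(g(y), s(y))`; `g` and `s` are estimated by binning feature
samples against distance (equal-count bins, default 20, linear
interpolation between bin centers, unbiased bin standard deviations
floored at `1e-6` of the feature range). The expected normalized error

`chi* = \int dx \int dy (y - f*(x))^2 p(x|y) p(y) / (R^2/18)`

is evaluated by nested trapezoidal quadrature: a `(0, R]` grid in `y`, an
`x` grid extending five maximal dispersions beyond the range of `g`
(2048 points each by default, evaluated in chunks). Convergence is
assessed by grid doubling until consecutive estimates agree within 1e-3
relative (up to three doublings; persistent disagreement raises with
diagnostics). Inside the quadrature, dispersions are floored at the
current x-grid spacing: empirical bins whose feature values coincide
(e.g. saturated intermittency far downwind) would otherwise produce
Gaussians far narrower than any affordable grid; the floor shrinks as
the grids refine, so the convergence loop bounds the smearing it
introduces. Where the evidence `p(x)` underflows, `f*` falls back to the
prior mean and the point is flagged.

`chi* = 1` for an uninformative feature, tends to 0 for a noiseless
strictly monotone one, and can never exceed 1 beyond quadrature error
because `f*` minimizes the expected squared loss. The Gaussian assumption
is an asymptotic (many-cycles-per-window) approximation; it is weakest
for the mean whiff duration, whose window average is markedly skewed in
sparse conditions, and results for that feature are flagged accordingly.

The model applies to individual features only; combinations and
non-Gaussian features would need a different likelihood treatment.

## Numerical and design notes

- All randomness flows from named integer seeds; per-cell generator
  streams and per-replicate seeds derive from `numpy.random.SeedSequence`
  spawning, so identical configuration and seed reproduce results bit for
  bit (derived seeds stay below 2^31).
- Ground-truth feature laws describe the true on/off state (threshold
  -> 0). Adaptive-threshold estimates acquire a small selection bias —
  whiff samples below `cthr` are excluded — and window-level duration
  averages carry an O(1/window) boundary-truncation bias; the mean laws
  for `x1` and `x5` are exact at window level, the duration means are
  renewal-exact only asymptotically, and the dispersion laws are
  delta-method approximations.
- The closed-form kernel solution is verified against a second-order
  optimizer of the regularized objective. Gaussian kernel matrices of
  nearby points are numerically singular, leaving the minimizer
  indeterminate along near-null directions; the comparison therefore
  restricts to instances whose objective Hessian is well conditioned
  (width halved until the condition number is below 1e7), where agreement
  is at the 1e-10 level.
- At `lambda = 0` the solver checks conditioning explicitly and raises
  rather than returning an unstable interpolant; degenerate CV folds
  (constant outputs) are skipped with a warning; a zero chi denominator
  (constant test outputs) is an error, never a silent division.
- Experiment replicates share one plume realization and vary the window
  sampling (the study they emulate reports single-flow results); the
  sweep over sampling rate generates the plume at ten-fold temporal
  resolution and subsamples every tenth frame for the slow condition, so
  both conditions see the same underlying signal.
- Desk-scale problem sizes are the package defaults: a 64 x 17 grid with
  2700 frames, `N = 400`, `Nt = 800` windows of 100 samples for
  ranking-style experiments, `N = 5000` for the analytic-vs-empirical
  agreement check, and `N = 2000` for pair-versus-single comparisons.

## Known limitations

- The generator's independence across cells means detection-probability
  maps have no spatial coherence beyond the imposed radial laws.
- `x2` (peak slope) is nearly proportional to `x1` for internally flat
  whiffs (the onset step dominates), so the two intensity features are
  more redundant here than in a real flow; the optional within-whiff ramp
  decorrelates them slightly but is off by default.
- The exact slope operator of the original analysis is ambiguous between
  its summary and its methods description (onset derivative vs per-whiff
  peak); the per-whiff peak forward difference including the onset step
  is this package's documented choice.
- The expected-error model ignores crosswind structure: the likelihood is
  binned on downwind distance only, while features at fixed `z1` vary
  with `|z2|`; this inflates the apparent dispersion `s(y)` relative to a
  two-dimensional treatment.
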