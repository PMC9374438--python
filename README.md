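# plumeloc

Odor plumes in turbulent flow are intermittent: an animal (or sensor)
downwind of a source receives discrete whiffs of odor separated by blanks,
and both the *intensity* of the whiffs and the *timing* of the on/off
pattern change systematically with distance from the source. `plumeloc`
asks, quantitatively: from a short time series of odor concentration,
which summary statistics best predict source distance — and how close does
a learned predictor come to the best possible one?

The package is aimed at researchers in olfactory navigation, sensory
ecology and plume-tracking robotics who want a tested, reproducible
implementation of this feature-ranking analysis, together with a synthetic
plume generator that provides controlled study conditions with known
ground truth.

## What it implements

**Features.** A concentration record is binarized at the adaptive
threshold `c_thr = ½⟨c | c>0⟩` and segmented into whiffs and blanks. Five
scalar features summarize it: mean whiff concentration (`x1`) and mean
peak slope (`x2`) — the *intensity* features — and mean blank duration
(`x3`), mean whiff duration (`x4`) and the intermittency factor `x5`
(fraction of time above threshold) — the *timing* features, which are
exactly invariant to the unknown source strength because the threshold is
adaptive.

**Regression.** Distance is learned from feature vectors by Gaussian-kernel
ridge regression with the closed-form coefficients
`c = (K + λN I)⁻¹ y`, hyperparameters `(λ, σ)` selected by 4-fold cross
validation on an 8×8 log grid with 4×4 refinement. Performance is the
normalized test error

    χ = Σᵢ (yᵢ − f(xᵢ))² / Σᵢ (yᵢ − ȳ)²,

for which the trivial mean predictor scores exactly 1 and independent
random guessing scores 2 in expectation.

**Expected-error model.** For an individual feature, the best achievable
error is computed analytically: with sampling uniform over a detection
cone of length `R`, the distance prior is `p(y) = 2y/R²`; the feature's
conditional law is modeled as Gaussian `p(x|y) = N(g(y), s(y))` with
empirically binned `g, s`; the posterior-mean regression function
`f*(x) = ⟨y|x⟩` and the expected normalized error `χ*` follow by
quadrature. `χ* = 1` for an uninformative feature and `χ* → 0` for a
noiseless monotone one.

**Synthetic plumes.** A telegraph (alternating-renewal) generator with
per-whiff log-normal amplitudes emulates the statistical structure of a
real plume — cone-confined, intermittent, with independently tunable
intensity-decay and sparsity profiles — standing in for flow-resolving
simulation data at desk scale. Two presets bracket the conditions of
interest: `concentrated` (intensity features dominate) and `dilute`
(timing features dominate). See `docs/methods.md` for the model, its
assumptions and its limits.

## Worked example

```python
import numpy as np
from plumeloc import (
    PriorSpec, build_cone, detection_probability_map, estimate_likelihood,
    expected_error, generate_plume, sample_dataset,
)
from plumeloc.regression import fit_evaluate
from plumeloc.synthetic import dilute_config

plume = generate_plume(dilute_config(seed=42))
cone = build_cone(detection_probability_map(plume), plume)
print(f"cone: {cone.n_cells} cells, length R = {cone.R:.1f}")

dataset = sample_dataset(plume, cone, N=400, Nt=800, memory=100, seed=42)
for feat in ("x1", "x3", "x5"):
    rep = fit_evaluate(
        dataset.X((feat,), "train"), dataset.y("train"),
        dataset.X((feat,), "test"), dataset.y("test"),
        seed=42, features=(feat,),
    )
    lik = estimate_likelihood(
        dataset.X((feat,), "train").ravel(), dataset.y("train"), R=cone.R
    )
    chi_star = expected_error(lik, PriorSpec(cone.R)).chi_star
    print(f"{feat}: test chi = {rep.chi:.3f}   analytic chi* = {chi_star:.3f}")
```

prints

```
cone: 889 cells, length R = 63.5
x1: test chi = 1.018   analytic chi* = 0.979
x3: test chi = 0.748   analytic chi* = 0.758
x5: test chi = 0.774   analytic chi* = 0.733
```

Read: in this dilute plume, mean whiff concentration (`x1`) is no better
than guessing the average distance (χ ≈ 1 — intensity barely varies with
distance here), while blank duration (`x3`) and intermittency (`x5`)
predict distance well below the trivial error. The analytic χ* computed
from the binned feature statistics reproduces each feature's empirical
predictive power, which is the package's central consistency check: a
feature's usefulness is set by how sharply its distribution varies with
distance, not by the regression machinery.

A command-line interface mirrors the pipeline stages
(`plumeloc generate | features | cone | train | evaluate | error-model |
reproduce`); run `plumeloc --help`.

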