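# neurogeom

Statistical-manifold estimation and information geometry for labeled
neural population recordings.

## The problem

A population of N neurons responding to a behavioral or stimulus label
**x** (an animal's position and running speed, a grating orientation, a
ring angle) traces out a *statistical manifold*: a smooth mean surface
μ(**x**) in N-dimensional state space together with a label-dependent
noise covariance Σ(**x**),

    r(x) = μ(x) + ε,   ε ~ N(0, Σ(x)).

Most geometric and information-theoretic quantities of interest — the
manifold's size and local magnification, the noise projected onto its
tangent plane, the linear Fisher information
J&#7488;Σ⁻¹J that bounds decoding accuracy — are functionals of (μ, Σ).
Estimating Σ(**x**) from scattered labeled data is the hard part:
binning the label space throws away smoothness and leaves too few
samples per bin for a stable N×N covariance.

## The estimator: GKR

**GKR** (Gaussian process with kernel regression) fits the manifold in
two steps:

1. **Mean.** Each neuron is standardized and the mean surface is fitted
   by a shared-kernel Gaussian process — a product of squared-exponential
   kernels per label dimension (a sine-wrapped, periodic version for
   circular labels) plus a constant, with an inducing-point
   approximation for large datasets.
2. **Covariance.** With residuals εᵢ = rᵢ − μ(xᵢ), the covariance at any
   query is a normalized kernel-weighted average of residual outer
   products,

       Σ(x) = Σᵢ k_L(x, xᵢ) εᵢεᵢᵀ + ηI,
       k_L(x, x′) ∝ exp(−½ (x−x′)ᵀ L Lᵀ (x−x′)),

   where the upper-triangular precision factor L is learned by
   maximizing a held-out Gaussian log-likelihood (train/validation
   splits inside mini-batches, Adam updates). Evaluating the likelihood
   on the training points themselves would collapse Σ(xᵢ) onto the
   rank-one gram matrix, so the split is essential.

A sampling-based variant, **GKR-S**, drops the normality assumption and
resamples neighboring residuals with Silverman-bandwidth kernel weights.

## What is built on top

- `baselines` — bin averaging and Ledoit–Wolf shrinkage, the reference
  estimators, plus the relative-Frobenius-error benchmark protocol.
- `geometry` — tangent frames, manifold radius, lattice area,
  Riemannian metric J&#7488;J, linear Fisher information, total and
  tangent-projected noise, and the IFGC counterfactual (diagonalized Σ:
  same single-cell statistics, no cell-to-cell covariance).
- `decoding` — spatial coding accuracy (SCA): linear classification of
  two nearby spatial boxes per speed bin; the closed-form optimal
  accuracy Φ(√(Δμ&#7488;Σ⁻¹Δμ)/2); and the direction-averaged Fisher
  upper bound on SCA.
- `blea` — Bayesian linear ensemble averaging: per-resample Bayesian
  linear regressions of a metric on speed (evidence-maximized
  hyperparameters), collapsed by moment matching into one Gaussian
  posterior, with credible intervals and probability-of-direction
  tests.
- `topology` — Vietoris–Rips persistent homology (dimensions 0–2, an
  in-package cohomology-based engine), PCA + k-means cloud
  condensation, column-roll shuffle thresholds, and Betti counting —
  e.g. the toroidal signature (β₀, β₁, β₂) = (1, 2, 1).
- `preprocess` — spike trains → smoothed rate datasets, occupancy-
  corrected rate maps, gridness scoring, speed filtering,
  speed-balanced resampling, normality scans.
- `synthdata` — ground-truth fixtures: a 1-D ring population, a 2-D
  bump population, an independent-Poisson speed-gain (IPSG) grid-cell
  simulator, and a two-neuron correlated-noise toy.
- `workbench` — the end-to-end speed-modulation pipeline
  (resample → fit → geometry → BLEA) driven by a YAML config.

## Worked example

Fit GKR to 300 noisy samples from a known 10-neuron ring population and
benchmark it against Ledoit–Wolf shrinkage on 100 random query labels:

```python
import numpy as np
from neurogeom import synthdata
from neurogeom.gkr import fit_gkr
from neurogeom.baselines import fit_binned, relative_error
from neurogeom.geometry import tangent_frames, fisher_information

spec = synthdata.build_tuning_model("ring1d", n_neurons=10, seed=1)
data = synthdata.sample_dataset(spec, n_points=300, seed=3)
model = fit_gkr(data, seed=0)

rng = np.random.default_rng(7)
Xq = rng.uniform(0, 2 * np.pi, (100, 1))
mu_true, cov_true = synthdata.true_moments_batch(spec, Xq)
mu_hat, cov_hat = model.predict(Xq)

lw = fit_binned(data, bins_per_dim=20, shrinkage="lw",
                label_bounds=np.array([[0, 2 * np.pi]]))
mu_lw, cov_lw = lw.predict(Xq)

print(f"mean relative error      GKR {relative_error(mu_hat, mu_true):.3f}   "
      f"LW {relative_error(mu_lw, mu_true):.3f}")
print(f"covariance relative error GKR {relative_error(cov_hat, cov_true):.3f}   "
      f"LW {relative_error(cov_lw, cov_true):.3f}")

J = tangent_frames(model, Xq[:1], dims=(0,), h=1e-3)[0]
I, total = fisher_information(J, cov_hat[0])
print(f"linear Fisher information at theta={Xq[0,0]:.2f} rad: {total:.1f} rad^-2")
```

Output:

```
mean relative error      GKR 0.085   LW 0.236
covariance relative error GKR 0.504   LW 0.611
linear Fisher information at theta=3.93 rad: 333.5 rad^-2
```

GKR roughly halves the mean error and clearly improves the covariance
estimate relative to binned Ledoit–Wolf at this sample size; the Fisher
information says that, near θ ≈ 3.9 rad, an optimal unbiased decoder
reading this (synthetic) population could resolve the ring angle to
about 1/√333 ≈ 0.05 rad from a single population state.

A command-line front end mirrors the library
(`neurogeom synth|fit|sca|topology|run`); see `neurogeom --help`.

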