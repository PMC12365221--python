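# Methods

This note records the models implemented in `neurogeom`, the defaults
and units of the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish about real recordings.

## The statistical-manifold model

Neural states are modeled as Gaussian around a smooth mean surface,

r(**x**) = μ(**x**) + ε, ε ~ N(0, Σ(**x**)),

with **x** ∈ R^M the label (ring angle; 2-D position; position and
running speed) and r ∈ R^N the population state. Everything downstream
— manifold radius, lattice area, Riemannian metric JᵀJ, linear Fisher
information JᵀΣ⁻¹J, total and tangent-projected noise, decoding bounds
— is a functional of the pair (μ, Σ). The Gaussian assumption is a
modeling choice, not a claim about data; the GKR-S variant and the
`preprocess.normality_scan` diagnostic exist precisely to probe it.

## GKR

**Step 1 — mean.** Each neuron's trace is standardized to zero mean and
unit variance. All neurons share one GP prior with kernel

k(**x**, **x**′) = s_f · Π_d k_d(x_d, x_d′) + c,

where k_d is exp(−Δ²/2ℓ_d²) for ordinary labels and
exp(−sin²(πΔ/p_d)/2ℓ_d²) for circular labels of period p_d, plus
homoscedastic observation noise s_n. (A printed form of the periodic
kernel with sin(2πΔ/p) would have period p/2 and identify antipodal
ring angles; the standard p-periodic half-angle form is used.)
Hyperparameters (log s_f, log ℓ_d, log c, log s_n) are optimized by
L-BFGS-B; initialization: unit signal variance, length scales 20% of
each label's range, c = 0.1, noise variance 0.1. Datasets up to 600
points use the exact GP marginal likelihood; larger ones use the
collapsed variational bound of an inducing-point approximation
(default 200 inducing locations drawn as a random subset of training
labels and held fixed; the bound is evaluated on a subsample of at most
2,000 points, and the final predictive equations use every point).
Optimizing the inducing locations themselves was dropped: with
gradient-free optimization it multiplies the parameter count by the
label dimension times the inducing count for no measurable accuracy
gain on the fixtures here.

**Step 2 — covariance.** With residuals εᵢ = rᵢ − μ(xᵢ), the covariance
at a query is the normalized kernel average of residual gram matrices
plus a stability ridge η = 10⁻⁶:

Σ(**x**) = Σᵢ k_L(**x**, xᵢ) εᵢεᵢᵀ + ηI, Σᵢ k_L = 1.

The weight kernel's precision factor L (M×M upper triangular, so label
interactions are allowed) acts on *range-normalized* label differences;
this makes a single initialization (L = I, i.e. kernel width of one
label range per dimension) meaningful whether a label spans 2π radians
or 40 cm/s. L is trained to maximize the Gaussian log-likelihood of
held-out points: data are cut into batches of 3,000; each epoch draws a
fresh 0.66/0.34 train/validation split per batch; the validation
covariance is predicted from the train split's gram matrices; and Adam
(learning rate 5·10⁻², 20 steps per batch visit, 30 epochs, analytic
gradients — verified against finite differences) descends the
validation negative log-likelihood. Evaluating the likelihood on the
training points themselves has a degenerate optimum (Σ(xᵢ) → εᵢεᵢᵀ),
which is why the split exists. After training, all points join the
residual bank used for prediction. A single Adam update per batch visit
was also tried and simply leaves L at its initialization; the inner
steps are what make the fitted bandwidth data-dependent.

**GKR-S.** The normality-free variant keeps the GP mean and resamples
residuals of nearby labels with Gaussian kernel weights whose diagonal
bandwidths follow Silverman's rule,
√Σ_jj = (4/(d+1))^{1/(d+4)} n^{−1/(d+4)} σ_j; atoms with weight below
10⁻⁶ are dropped. Its analytic moments are the weighted residual mean
and weighted second moment (the weighted-mean term is treated as
negligible when forming the covariance).

## Reference estimators

Bin averaging partitions the label range into a regular grid (default
20 bins per 1-D label, 10×10 for 2-D) and uses per-bin sample moments;
the Ledoit–Wolf variant shrinks each bin's sample covariance toward
(tr S/N)·I with the standard shrinkage intensity. Estimators are scored
by the mean relative Frobenius error ‖M̂−M‖_F/‖M‖_F over 100 random
query labels against the synthetic ground truth, for μ, Σ, JᵀJ, the
Fisher matrix and the precision matrix. Queries landing in empty bins
are served by the nearest occupied bin (logged).

## Geometry

Tangent vectors are central finite differences of the fitted mean
(default step: 1% of each label's range; one-sided at hard domain
boundaries). Manifold (speed-slice) radius is the mean distance of 500
uniformly sampled spatial locations' mean states to their centroid.
Projected noise uses the column-*normalized* (not orthogonalized)
Jacobian exactly; for highly correlated tangent directions this can
double-count noise, so an orthonormal variant sits behind a flag and is
what the projected ≤ total invariant is asserted against. The IFGC
(independent-firing) counterfactual zeroes all off-diagonal covariance
entries at prediction time; it preserves total noise identically and
equals what within-condition trial shuffling converges to.

## Decoding

SCA follows the two-box protocol: per speed bin of 5 cm/s, 300 random
centers; boxes of edge 10 cm displaced ±5 cm along a random direction;
class-balanced subsampling; 0.67/0.33 train/test split; logistic
regression with C = 1 (SVM and perceptron selectable); the bin's SCA is
the mean test accuracy over centers with at least 50 points. The
optimal linear accuracy for two Gaussian classes with shared covariance
is Φ(√(ΔμᵀΣ⁻¹Δμ)/2); for symmetric boxes this becomes the
direction-averaged bound ∫ Φ(√(δxᵀ I δx)) dθ/2π, evaluated by Monte
Carlo over isotropic directions rescaled to length δl. Only the exact
integral is implemented; the small-δl Taylor form is asserted only
through its 0.5 intercept, because the linearized coefficient depends
on an isotropy assumption that need not hold.

## BLEA

Per resampled dataset, a Bayesian linear regression t = wᵀ(v, 1) + ε
with prior w ~ N(0, α⁻¹I) and noise precision β; α and β maximize the
evidence by the standard fixed-point iteration (tolerance 10⁻⁶, 200
iterations max). The iteration is *initialized at the least-squares
solution* (α = 2/‖m_OLS‖², β = n/SSE_OLS): starting from α = 1 with a
metric riding on a large offset (total noise ~10³–10⁴) converges to a
degenerate all-noise fixed point that trades the intercept for the
slope. Per-dataset posteriors are collapsed by exact moment matching:
ensemble mean = mean of means; ensemble covariance = mean of
covariances + between-mean scatter; predictive noise = mean of β_s⁻¹.
Because the scatter term never shrinks with the number of resamples of
the *same* underlying data, pooling cannot fabricate certainty — the
calibration test in the suite checks exactly this. Significance is
reported as probability of direction p_d and two-sided p = 2(1 − p_d).

## Synthetic fixtures

*Ring*: N = 10 neurons, von Mises tuning of width σ = 0.3 normalized to
peak gain gᵢ ~ U(0.5, 1.5), centers 2πi/N; covariance Σ = LLᵀ with
L_ij = (α μᵢ + ν)e^{−γ|i−j|}, (α, ν, γ) = (0.2, 0.05, 1); default
dataset 300 points. *Bump*: Gaussian receptive fields on [−1, 1]²,
width 0.3·λᵢ, λᵢ ~ U(0.5, 1.5), (α, ν, γ) = (0.5, 0.1, 1). *IPSG*: 10
independent Poisson grid cells, three-cosine hexagonal rate maps of
period π on [−π, π]² with offset 4, shared saturating speed gain
f(v) = 20(1 − e^{−v/10}), speeds uniform on [0, 40]; counts use a unit
time window Δt = 1 (no window is canonical; it only rescales the noise
level). Closed-form speed curves for radius, total noise and Fisher are
evaluated on a 200×200 quadrature grid. *Two-neuron toy*: class means
(1,0)/(0,1), unit-variance noise with correlation ρ; Fisher = 2/(1−ρ).

These fixtures have exactly Gaussian (or Poisson) noise, stationary
tuning, and uniformly sampled labels. Passing tests on them establishes
correctness of the estimators and analyses under the model's own
assumptions — not robustness to non-stationarity, theta modulation,
head-direction confounds, or the strongly non-Gaussian firing of real
populations (the normality scan exists to quantify that departure).

## Topology

The Vietoris–Rips engine computes Z/2 persistence in dimensions 0–2:
union-find for H0, and for H1/H2 the persistent-cohomology reduction
with implicit cofacet enumeration, zero-persistence (emergent) pair
shortcut, and clearing — the standard algorithmic recipe that keeps
Rips persistence tractable (the column count is the number of
p-simplices, not (p+1)-simplices). It is validated bar-for-bar against
an exhaustive boundary-matrix reducer on random clouds. The filtration
is capped at the enclosing radius (beyond which the complex is a cone);
bars alive at the cap are reported as infinite and, for thresholding,
counted with length equal to the cap. `sparse_eps` optionally prunes
points closer than ε times the mean nearest-neighbor spacing (a greedy
net); by stability this moves bar endpoints by at most twice the
pruning radius, and it is a no-op on already-condensed clouds.

Pipeline: project the cloud to 6 PCs, condense with k-means (default
200 centers, 10 restarts), compute the barcode, and count bars longer
than a shuffle threshold: each state-matrix column is circularly rolled
by an independent random offset, the same condense-and-barcode recipe
is applied, and the maximum *finite* bar length over 20 repeats is the
threshold. (Including the essential H0 bar, whose capped length is the
enclosing radius itself, would make the threshold equal the cap and
erase every count; shuffle thresholds therefore use finite-death bars
only.) Exact dimension-2 persistence is quadratic-to-cubic in the
number of centers; ~200 centers keeps a full 21-barcode signature
(data + 20 shuffles) at around two to three minutes on one CPU, and on
the 1,000-point torus fixture leaves the two 1-dimensional bars
(length ≈ 1.2) and the 2-dimensional bar (≈ 1.0) well clear of the
shuffle threshold (≈ 0.7).

## Preprocessing

Spikes are binned at 10 ms, converted to rates, and smoothed with a
20 ms Gaussian; positions are linearly interpolated to bin centers;
speed is the L2 norm of the central difference over two bins. Rate maps
use 3 cm bins with 8.25 cm Gaussian smoothing of both the rate image
and the visit mask, and their ratio corrects occupancy bias. Gridness
works on the spatial autocorrelogram computed as a Pearson correlation
*per lag* (over the overlapping pixels, zero lag exactly centered) —
an unnormalized autocorrelation is dominated by the rotation-symmetric
overlap taper and scores even a perfect hexagonal field near zero. The
autocorrelogram is masked to an annulus (outer circle diameter = map
edge, inner area 15% of the outer, removing the central peak) and
correlated with its 30/60/90/120/150° rotations over annulus-interior
pixels; score = mean(60°, 120°) − mean(30°, 90°, 150°). An optional
linear-ramp padding (for fields cut off at the arena wall) is off by
default. An ideal hexagonal map scores ≈ +1.5, a square lattice ≈ −0.4,
a radially symmetric blob ≈ 0. Speed filtering
keeps [5, 45) cm/s (closed-open; the printed exclusion rule is
ambiguous at the endpoints, so the convention is fixed and tested) and
cells with gridness ≥ 0.1. Balanced resampling draws
K = min(smallest speed-bin count, 10,000) points per 5 cm/s bin without
replacement, 50 replicates by default, with an optional label-timestamp
permutation for shuffled controls.

## Problem sizes in the checked examples

The test suite and acceptance script run everything at desk scale,
chosen to exercise the full pipelines while staying comfortably on one
CPU: ring benchmarks at T ∈ {100, 300, 1000} over 10 seeds; the IPSG
pipeline at 3,500–4,000 simulated points with 3–4 resampling replicates
per condition and correspondingly shortened GP/covariance optimization
schedules; torus clouds of 1,000 points condensed to 200 centers. The
package defaults (50 replicates, 10,000-point cap, 200 inducing points,
30 covariance epochs) are what an analysis of a full recording would
use.
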