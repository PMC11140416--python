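# Methods

## Model

A cell's center-of-mass motion in each spatial direction is modeled by the
generalized Langevin equation (GLE) written per unit mass,

    v̇(t) = −∫₀ᵗ Γ(t−t′) v(t′) dt′ + F_R(t),

with a single effective memory kernel Γ(t) and a Gaussian random force
F_R whose strength is set by the mean-squared velocity B = ⟨v²⟩.  The
package deliberately works with *one* effective kernel: from trajectories
alone only the surrogate kernel that reproduces the velocity
autocorrelation function (VACF) is identifiable; separate friction and
random-force kernels of a nonequilibrium model are not.  The x and y
motions are treated as independent realizations of the same process, so
all correlation estimates are averaged over the two components.

The motion is assumed to be a **stationary Gaussian process**.  Everything
downstream rests on this: the two-point statistics are then fully
determined by the VACF, and the conditional law
p(v₂ | v₁, lag) is Gaussian with mean v₁·C(lag)/C(0) and variance
C(0) − C(lag)²/C(0).  The `correlations` module provides moment-based
diagnostics (per-cell standardized velocity distributions, excess
kurtosis, binned conditional moments) to check this on data before
trusting the parameters.

The kernel is parameterized as

    Γ(t) = 2a δ(t) + b e^{−t/τ} cos(Ωt),

with δ-peak amplitude a (1/s; instantaneous friction), oscillation
amplitude b (1/s²), decay time τ (s), and frequency Ω (1/s).  The δ-peak
contributes only to the initial grid value, Γ(0) = 2a/Δ + b, where Δ is
the sampling step.  A pure persistent-random-walk cell would have b = 0;
oscillating kernels arise from elastically coupled internal degrees of
freedom (e.g. flagellar beating).

## Estimators

Velocities live on half steps, v_{i+1/2} = (x_{i+1} − x_i)/Δ.  The VACF
estimator at lag i averages all n_v − i overlapping products of the n_v
velocities of a component (the standard stationary time average; the count
at each lag is stored).  The MSD uses all overlapping start points the
same way.  C_vv(0) is the estimator of B.

The kernel is obtained by discretizing the Volterra relation
C(t) − C(0) = −∫₀ᵗ C(s) G(t−s) ds, G(t) = ∫₀ᵗ Γ(s) ds, with G on half
steps (G is odd) and C on full steps (C is even):

    G_{i+1/2} = 2(C₀ − C_{i+1}) / (Δ(C₁ + C₀))
                − Σ_{j=1}^{i} G_{i−j+1/2} (C_{j+1} + C_j)/(C₁ + C₀),

an explicit forward recursion, followed by the central difference
Γ_i = (G_{i+1/2} − G_{i−1/2})/Δ with Γ₀ = 2G_{1/2}/Δ.  The recursion is
the *exact* inverse of its own discretization (the test suite checks the
back-substitution defect at machine precision) and is second-order
accurate in Δ against the continuum kernel: halving Δ reduces the error
~4×.  Its absolute accuracy is limited by the dimensionless product ΩΔ —
the relative kernel error scales like (ΩΔ)²/12, about 0.5–1% at
Δ = 0.002 s and Ω ≈ 120–200 s⁻¹.  No smoothing or regularization is
applied to the recursion; noise is controlled upstream (position
averaging) and downstream (fitting only a short horizon).

**Known bias of the direct route.**  Measured velocities are finite
differences, so the empirical VACF equals the second-difference stencil of
the true MSD, not the continuum VACF.  At lags 0 and 1 this bias is a few
tenths of a percent of C(0) — small in absolute terms, but the Volterra
pivot divides by the *difference* C₀ − C₁, which amplifies it into a
systematic error of order 30% in the δ-amplitude a (parameters b, Ω, B
are barely affected).  The discretized noisy-VACF fit described below
models the measurement chain exactly and therefore recovers a without
this bias; treat the direct-fit a as an effective, Δ-dependent parameter.
Classification is insensitive to this because the bias is smooth in the
underlying parameters and common to all cells analyzed at the same Δ.

## Forward model and fits

The model VACF solves the linear Volterra ODE obtained by inserting the
parametric kernel.  Two independent exact routes are implemented and used
as mutual oracles (agreement ~1e-12): (i) augmenting the convolution with
two exponential-oscillator states gives a 3-variable linear ODE propagated
by its matrix exponential; (ii) the Laplace-domain denominator is the
cubic (s+a)((s+1/τ)²+Ω²) + b(s+1/τ+cΩ), whose roots give
C(t) = Σ R_k e^{r_k t} in closed form (c is the sin-correction
coefficient, see the simulator below).  The MSD follows as
2∫₀ᵗ (t−s) C(s) ds, again in closed form.  The Markovian limit b = 0 is
special-cased to the exact exponential.  The closed-form MSD of the
supplementary literature is intentionally *not* transcribed; the forward
solver replaces it and is cross-validated by the dual-route agreement.

**Direct kernel fit.**  Bounded nonlinear least squares of the parametric
kernel against the first 0.2 s of the extracted Γ (Γ₀ included).  Bounds:
τ ∈ [0.05, 3] s, Ω ∈ [20, 250] s⁻¹, and the two additive contributions to
Γ₀ each within [0.1%, 99.9%] of the measured Γ₀ (i.e. 2a/Δ and b; the
constraint is stated in terms of Γ₀ because a and b carry different
units).  The oscillatory model is multimodal in Ω, so the fit multi-starts
from 8 Latin-hypercube draws inside the bounds (fixed seed) plus a
data-driven start with Ω at the kernel's first minimum.  Parameter
standard deviations come from the diagonal of s²(JᵀJ)⁻¹; active bounds
and ill-conditioned covariances are flagged, never silently ignored.

**Discretized noisy-VACF fit.**  Localization noise (i.i.d. Gaussian
position error of width σ_loc) adds 2σ_loc² to the MSD at every nonzero
lag; sampling at finite Δ means the measured VACF is the stencil
(M_{i+1} − 2M_i + M_{i−1})/(2Δ²) of that noisy MSD, with the even
extension M_{−1} = M_1 at i = 0 (the MSD of a stationary process is even;
the choice is ours, the source material is silent).  Pure noise therefore
has the signature (+2σ²/Δ², −σ²/Δ², 0, …).  The fit minimizes the
unweighted squared residual of this model against the measured VACF up to
0.2 s over (a, b, τ, Ω, B, σ_loc), with σ_loc ∈ [0, 1] μm (upper bound is
an artifact decision: generous against pixel-scale noise while preventing
the noise/signal swap degeneracy) and B ∈ [10⁻³, 10]·C₀.  This fit is a
validation tool; the classification pipeline clusters the direct-fit
parameters.

## Simulator (ground-truth factory)

The GLE with kernel Γ(t) = 2aδ(t) + b e^{−t/τ}[cos(Ωt) + (1/(τΩ)) sin(Ωt)]
is exactly the observed coordinate of two harmonically coupled degrees of
freedom (masses m, m_y, frictions γ_x, γ_y, coupling K, temperature k_BT)
with the map a = γ_x/m, b = K/m, τ = 2m_y/γ_y, Ω = √(K/m_y − 1/τ²); the
inverse uses the gauge m ≔ 1 since only ratios are identifiable.  When
τΩ ≳ 100 the sin correction is ≤ 1% and the simulator's kernel matches
the pure-cosine fitting model to ~1%; the mapping flags larger
corrections.  The hidden mode must be underdamped (K/m_y > 1/τ²);
overdamped requests raise an error naming the critical coupling.

The coupled system is a 4-dimensional linear SDE per component, so its
transition over any step is exactly Gaussian: z_{n+1} = E z_n + ξ with
E = e^{Mh} and cov(ξ) from the Van Loan block exponential.  The update is
exact at any step size — integrator bias is removed from all oracles by
construction.  An internal substep keeps h·(fastest rate) < 0.1 purely as
a resolution contract; output is decimated to Δ.  Runs start from the
stationary Gibbs distribution (v, v_y, x−y independent Gaussians), so
correlation estimates need no equilibration discard.  Identical seeds give
bit-identical output on one platform.

`generate_population` draws per-cell parameters log-normally (median =
population center; default relative spread 0.15) and redraws values that
leave the identifiable box τ ∈ [0.05, 3], Ω ∈ [20, 250] when the center
is inside it, so synthetic ground truth stays recoverable by the bounded
fit.  Defaults emulate the experimental regime the package targets:
Δ = 0.002 s, trajectories of order 10³–10⁴ steps (10⁵–10⁶ in the
validation studies), speeds of tens of μm/s, σ_loc ≈ 0.02 μm, and two
sub-populations with distinct (a, b, τ, Ω, B).  What the generator does
*not* emulate: aging/nonstationarity, switching between modes, gaps and
tracking failures, non-Gaussian heavy tails, and cell–cell interactions —
passing tests therefore demonstrate correctness of the estimators under
the model's assumptions, not robustness to their violation.

## Clustering

Features are (a, b, τ, Ω, B), each divided by its median across cells
(recorded for inversion; idempotent).  k-means is plain deterministic
Lloyd iteration with Euclidean distance; an emptied cluster is re-seeded
at the farthest point whose donor cluster can spare it.  X-means starts
from k = 2 (two supplied cells as centers), tentatively bisects every
cluster along its principal axis, and accepts a split iff a model-selection
score improves on that cluster's points; it stops when no split is
accepted or k = 20.

The default split score is a two-part **description length** under a
noiseless diagonal-Gaussian model: data bits ½n Σ_d log₂(2πe σ̂_d²) plus
model bits for centers/noise levels and n·log₂k assignment indices.  The
diagonal (per-axis) variance matters: physical parameters have very
different scatter even after median rescaling, and a spherical score
would split any anisotropic single population along its widest axis.  A
BIC variant (diagonal Pelleg–Moore form) is available via
`criterion="bic"`.  The cited description-length criterion is defined in
external references without formulas in the source material, so the score
implemented here is the package's own realization; conclusions are only
claimed for well-separated data, where any sane criterion agrees.

The consensus protocol runs X-means once per unordered pair of cells as
initial centers — n(n−1)/2 runs, 1711 for 59 cells — compares partitions
up to label permutation (canonical form: relabel by first occurrence),
and returns the most frequent partition with its support fraction.  Ties
are broken by the lexicographically smallest canonical labeling and
flagged.  The whole procedure is deterministic for a fixed feature table.
Accuracy against a ground-truth column is the best label-permutation
match (Hungarian assignment on the confusion matrix).

## Numerical choices and degenerate inputs

- Units are fixed internally to seconds and micrometers; readers convert.
- Gaps/NaNs and non-uniform sampling (tolerance 10⁻⁶ relative) are hard
  ingest errors — never interpolated, because every estimator assumes
  uniform complete sampling.
- Position smoothing default: running mean over 2 consecutive positions,
  recorded in provenance; window 1 disables it.
- Volterra recursion refuses a numerically zero pivot C₁ + C₀ (perfectly
  anticorrelated adjacent velocities).
- `conditional_velocity` rejects |C(lag)| > C(0) (estimator noise can
  break positive semidefiniteness at long lags; truncate before use).
- Extraction horizon and fit window default to 0.2 s; extraction beyond
  the horizon amplifies estimator noise without informing the fit.
- Fits flag active bounds, ill-conditioned covariances, and
  under-determined windows instead of failing or silently succeeding.

## Validation problem sizes

The shipped validation studies use: kernel round trips on exact model
VACFs at Δ = 0.002 s and 0.001 s (horizon 0.2 s); one 10⁶-step cell for
equipartition, VACF equivalence, and the conditional-Gaussian law; a
40-cell cohort at 5·10⁵ steps for parameter recovery; 5·10⁵ steps with
σ_loc = 0.02 μm for noise recovery; 40-cell parameter clouds over 10
seeds for the clustering protocol; and a 59-cell cloud for the consensus
run count.  These sizes give Monte-Carlo errors comfortably below the
asserted tolerances while keeping the full battery at a few minutes on
one CPU.

## Known limitations

- The direct-fit δ-amplitude a inherits a finite-Δ bias (see above); use
  the noisy-VACF fit when an unbiased a matters.
- τ is the least identifiable parameter: within the 0.2 s window the
  envelope decays by at most a factor ~55 (often much less), so its
  relative error is an order of magnitude larger than that of b or Ω.
- The extraction cannot distinguish friction memory from random-force
  memory; all parameters describe the effective surrogate kernel.
- Long-memory (aging) dynamics would require far longer trajectories than
  the defaults and are not modeled by the simulator.
- 3-D trajectories, tracking/segmentation, and confining-potential
  variants of the GLE are out of scope.
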