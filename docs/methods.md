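# Methods

## Model

A compositional time series x_t (T observations of p strictly positive
parts) is expressed in isometric log-ratio coordinates
x_t^ilr = Vᵀ clr(x_t), where clr(x)_i = ln x_i − (1/p) Σ_j ln x_j and V
is a p×(p−1) contrast matrix with orthonormal, zero-sum columns.  The
default is the pivot basis, whose column j is
√((p−j)/(p−j+1)) · (0,…,0, 1, −1/(p−j), …, −1/(p−j)) with j−1 leading
zeros; its first coordinate is √(p/(p−1)) · clr₁ and therefore
aggregates all relative information about the first part.  Any other
orthonormal basis is accepted; two such coordinate systems differ only
by an orthogonal rotation, so (by the affine equivariance of the
estimators) the basis choice changes the recovered sources at most in
sign and order.

In ilr space the blind source separation model is

    x_t^ilr = μ + Ω z_t,

with full-rank mixing matrix Ω ∈ R^{d×d}, d = p−1, and latent sources
z_t with E z_t = 0, E z_t z_tᵀ = I.  The model is identified only up to
sign and permutation of the components (and scale, for nonstationary
variants); deterministic conventions resolve this (below).

## Estimators

All estimators build moment matrices from the (coordinate) series and
diagonalize them.  Autocovariances are
S_τ = E[(x_t−μ)(x_{t+τ}−μ)ᵀ]; local versions S_{T,τ} restrict t and
t+τ to a time interval T and centre with the interval mean.  For the
whitened series x^st = COV^{−1/2}(x−μ̂), the fourth-order cross-moment
matrix is B_τ = E[x^st_{t+τ} x^stᵀ_t x^st_t x^stᵀ_{t+τ}] and the
cross-cumulant matrices are
C^{jk}_τ = E[x_{t+τ} x_tᵀ E^{jk} x_t x_{t+τ}ᵀ] − S_τ(E^{jk}+E^{kj})S_τᵀ
− tr(E^{jk}) I with E^{jk} = e_j e_kᵀ.

* **AMUSE(τ)** — generalized eigendecomposition of (COV, sym S_τ);
  requires distinct eigenvalues (distinct lag-τ autocorrelations).
* **SOBI(𝒯)** — whiten, then orthogonal approximate joint
  diagonalization (AJD) of the symmetrized whitened S_τ, τ ∈ 𝒯
  (default {1,…,6}).
* **gFOBI(𝒯)** — AJD of the B_τ, τ ∈ 𝒯 (default {0,…,6}); 𝒯 = {0}
  gives FOBI.
* **gJADE(𝒯)** — AJD of all p² matrices C^{jk}_τ per lag; 𝒯 = {0}
  gives JADE.
* **vSOBI(𝒯, G)** — maximizes
  Σ_τ Σ_i (E[G(u_iᵀx^st_t)G(u_iᵀx^st_{t+τ})] − E[G(u_iᵀx^st_t)]²)² over
  orthogonal U, G(y) = y² (default) or log cosh y.
* **NSS-SD(T₁,T₂)** — generalized eigendecomposition of the two interval
  covariances (defaults: the two halves of the range).
* **NSS-JD(K)** — whiten globally, AJD of the K interval covariances
  (default K = 6).
* **NSS-TD-JD(K,𝒯)** — AJD over all interval × lag local
  autocovariances (block-stationary sources).
* **NSS-SOBI-gFOBI(K,𝒯₁,𝒯₂,weights)** — the combined estimator: per
  interval T_i the stack holds S_{T_i,τ} for τ ∈ 𝒯₁ *and* B_{T_i,τ} for
  τ ∈ 𝒯₂ (both computed from the globally whitened series; the interval
  B matrices reuse the global whitening and the interval's own pairs).
  Weight schemes: `equal` (α_j = 1), `kurtosis` (B matrices divided by
  p+2, the value that makes the lag-0 fourth-moment matrix estimate the
  covariance at a Gaussian model), `maxnorm` (α_j = 1/max|V_j| when that
  max exceeds 1, else 1 — large matrices are damped without up-weighting
  near-zero ones).  Weights scale the matrices before the AJD criterion,
  so the effective weight on each squared diagonal term is α_j².

The non-combined defaults mirror the comparison study (SOBI lags 1–6,
gFOBI lags 0–6, K = 6, combined lag sets 0–6).

## Optimization

**Jacobi AJD.**  The sum of squared diagonals Σ_j Σ_i (u_iᵀ M_j u_i)² is
maximized by cyclic sweeps over index pairs (i,k); each 2×2 subproblem
has a closed-form optimal angle — the principal eigenvector of the 2×2
form built from the per-matrix diagonal difference and twice the
off-diagonal, with the sign convention |θ| ≤ π/4.  Sweeps stop when the
largest rotation angle falls below 1e−10, or after 100 sweeps.  For p=2
the result matches an exhaustive angle scan to 1e−6 (tested).

**GEVD.**  Two-matrix problems are solved by whitening with the
symmetric inverse square root of the first matrix and
eigendecomposing the second in that basis; rows satisfy Γ A Γᵀ = I and
Γ B Γᵀ = diag(descending).

**vSOBI fixed point.**  The criterion gradient with respect to the rows
of U is assembled from lagged means of G and its derivative; the next
iterate is the orthogonal polar factor of the gradient matrix.
Convergence is declared when successive iterates differ (after sign
alignment) by < 1e−6 in Frobenius norm; at most 1,000 iterations; the
best of 5 seeded random orthogonal starts plus the identity start is
returned; non-convergence of every restart is flagged on the result, not
raised.

**Conventions.**  Rows of the unmixing matrix are ordered by the
method's separation statistic (descending eigenvalues for
AMUSE/NSS-SD, descending per-component criterion contribution for AJD
methods); signs are fixed so each row's largest-magnitude entry is
positive; NSS-SD sources are rescaled to unit overall variance (the NSS
model does not identify scale; whitening-based methods deliver unit
variance automatically).  A `gap_warning` diagnostic flags nearly tied
separation statistics (overall spread below 20% of the statistic's
magnitude — sized to sampling noise at series lengths in the thousands —
or a consecutive gap below 0.1% of the spread); it is advisory.

**Equivariance.**  For a full-rank transform A of the data, every
estimator returns the same sources up to sign and permutation; this is
exact (tested at 1e−6, and 1e−3 for the iterative vSOBI) for all methods
except the maxnorm-weighted combined estimator, whose weights
1/max|V_j| depend on matrix entries and therefore change slightly under
the rotation relating the two whitened series.  The resulting deviation
is small (order 1e−2 on mixed data) but not zero; `equal` and
`kurtosis` weights are exactly equivariant.

## Missing time points

Observations are placed on a declared regular grid (integer index, or a
datetime grid such as "10min"); gaps are allowed.  Every lagged
statistic averages over exactly those pairs (t, t+τ) whose grid
positions differ by τ and were both observed, with the number of valid
pairs as divisor (equal to T−τ, or |T|−τ per interval, for complete
data).  The complete-data and gap-aware paths coincide when nothing is
missing.  Whitening requires the covariance to be numerically positive
definite (smallest eigenvalue above 1e−10 of the largest); otherwise an
error advises PCA pre-reduction.

## Pipeline

`decompose` / `CompositionalBSS.fit` chain ilr representation, optional
covariance PCA on the ilr coordinates (no per-coordinate scaling — ilr
coordinates share a unit; the smallest q reaching the explained-variance
threshold is kept), the chosen estimator, and interpretation outputs.
The clr loading matrix is Γ Wᵀ Vᵀ (W = PCA loadings, identity when PCA
is off) — the unique linear map consistent with
sources ← scores ← ilr ← clr; its rows sum to zero.  Reconstruction
inverts each fitted step (sources → scores → ilr → closed composition)
and reproduces the PCA-truncated ilr series exactly; component subsets
are selected explicitly by the user (no automatic threshold).
Compositions are never forced to a constant sum on input; closure is
applied only to back-transformed output.  Nonpositive entries are a hard
error by default; an explicit option applies multiplicative replacement
(per part, 65% of the smallest observed positive value) with a loud
warning.

## Synthetic processes and the simulation study

The generator emulates three latent scenarios on the ilr scale, each
standardized to unit sample variance per source:

* **LP** — stationary ARMA processes simulated by filtering innovations
  with a burn-in of 10·(order+1)+100.  Defaults for m sources: AR(1)
  coefficients evenly spread over [0.2, 0.9], with an MA(1) θ = 0.3
  added on even-indexed sources so the autocorrelation functions are
  distinct.
* **SV** — GARCH(1,1) recursions σ²_t = ω + a ε²_{t−1} + b σ²_{t−1}
  with ω = 1−a−b (unit unconditional variance) and a burn-in of 500.
  Defaults: (a, b) pairs spread over a ∈ [0.05, 0.2], b from 0.9 down to
  0.7, keeping a+b ≤ 0.97.  A log-variance AR(1) family
  (h_t = μ + φ(h_{t−1}−μ) + σξ_t, z_t = e^{h_t/2}η_t) is available as an
  alternative.
* **MIX** — half LP, half SV sources.

Settings: 1 — Gaussian innovations, 4 latent components; 2 — logistic
innovations scaled by √3/π to unit variance (excess kurtosis 1.2);
3 — Gaussian, 8 components.  Sources are mixed in ilr space (identity
mixing by default; equivariance makes the mixing matrix irrelevant to
performance) and mapped through the inverse ilr transform, so study runs
exercise the full representation chain.  A blockwise variance-modulated
generator (log-uniform block standard deviations on an AR(1) base)
provides nonstationary sources for exercising the NSS estimators.

Performance is scored by the minimum distance index
MD(Γ̂,Ω) = (p−1)^{−1/2} inf_C ‖C Γ̂ Ω − I‖_F over matrices C with
exactly one nonzero per row and column.  The inner problem is solved
exactly: per-row optimal scales in closed form, then optimal assignment
via a linear-assignment solver; results match exhaustive permutation
enumeration (tested to 1e−10 for p ≤ 4).

The study harness derives one seed per (cell, replicate) from the master
seed by a counter-based scheme, reports the mean MD and its Monte-Carlo
standard error per cell, and runs at 200 replicates by default (standard
errors below 0.01 for the cells reported); sample sizes up to T = 10,000
at p = 4 and 8.  These sizes keep a full run in the low minutes on one
CPU while leaving the Monte-Carlo error an order of magnitude below the
effect sizes of interest.

**What the generator does not emulate.**  Real compositional sensor
series have smoothly varying spectra and strong cross-part dependence at
fixed time (here induced only through mixing), regime changes, drifting
means, measurement error on the simplex, and irregular missingness
(here: deterministic injected gaps).  Passing tests therefore establish
correctness of the transforms and estimators and qualitative method
orderings under the stated process classes — not performance guarantees
on any particular real data set.

## Known limitations

* The maxnorm weight scheme is only approximately affine equivariant
  (see above).
* Mean MD values for individual simulation cells depend visibly on the
  generating-process parameters (persistence and kurtosis spreads);
  qualitative orderings across methods are far more stable than the cell
  values themselves.  Near-Gaussian stochastic-volatility sources
  (small ARCH coefficient) are weakly identified by fourth-moment
  methods at realistic sample sizes.
* No asymptotic standard errors for the unmixing estimates; no
  lag/interval selection machinery; non-grid (truly irregular) sampling
  is out of scope — timestamps must sit on a declared regular grid.
* Forecasting of the recovered sources is left to the user (any
  univariate toolbox applies); reconstruction accepts predicted source
  values for mapping back to the simplex.
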