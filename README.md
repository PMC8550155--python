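# ctsbss — blind source separation for compositional time series

Many monitored systems report *compositions* over time: vectors of
strictly positive parts (relative abundances, spectral fractions,
chemical proportions) where only the ratios between parts carry
information.  Examples range from longitudinal microbiome profiles to
stream-water absorbance spectra sampled every few minutes.  Such series
are intrinsically multivariate and live on the simplex, so standard
multivariate time-series machinery cannot be applied directly — and
fitting a full multivariate model in tens or hundreds of dimensions is
rarely practical anyway.

`ctsbss` decomposes a compositional time series (CTS) into a small number
of latent, uncorrelated univariate series that can be inspected, modelled
and forecast one at a time:

1. express the CTS x_t in isometric log-ratio (ilr) coordinates
   x_t^ilr = Vᵀ clr(x_t), with V a p×(p−1) contrast matrix with
   orthonormal zero-sum columns (pivot coordinates by default);
2. assume a blind source separation (BSS) model in that Euclidean space,
   x_t^ilr = μ + Ω z_t, with full-rank mixing matrix Ω and latent
   uncorrelated sources z_t;
3. estimate the unmixing matrix Γ ≈ Ω⁻¹ (up to sign/permutation, and
   scale for nonstationary models) from moment matrices of the series;
4. interpret components through the clr loading matrix Γ Vᵀ, or map
   selected components back to the simplex.

## Estimators

All nine classical and recent unmixing estimators reduce to (approximate)
joint diagonalization of moment matrices and are provided behind one
interface:

| model assumption | estimators | diagonalized matrices |
|---|---|---|
| stationary, serially correlated (SOS) | `amuse`, `sobi` | lagged autocovariances S_τ |
| stochastic volatility (SV) | `gfobi`, `gjade`, `vsobi` | fourth-order lagged moment/cumulant matrices B_τ, C^{jk}_τ (vSOBI: a nonquadratic lagged-correlation contrast) |
| nonstationary variance (NSS) | `nss_sd`, `nss_jd`, `nss_td_jd` | interval covariances S_{T_i,τ} |
| any mixture of the above | `nss_sobi_gfobi` | weighted stack of interval S_{T_i,τ} *and* interval B_{T_i,τ} |

The weighted combined estimator `nss_sobi_gfobi` jointly diagonalizes,
per time interval T_i, both the local autocovariances (lags 𝒯₁) and the
local fourth-order cross-moment matrices (lags 𝒯₂), with weight schemes
`equal`, `kurtosis` (B matrices divided by p+2) or `maxnorm`
(α_j = 1/max|V_j| when that max exceeds 1).  It needs no prior commitment
to a time-series model class, which matters for environmental and omics
series where the latent dynamics are unknown.

Missing time points are supported throughout: observations sit on a
declared regular grid and every lagged statistic uses only pairs of
observations exactly τ grid steps apart.

## Worked example

Simulate a 5-part composition driven by four latent series (two linear
processes, two GARCH(1,1) stochastic-volatility processes), then recover
the sources with the combined estimator:

```python
from ctsbss import decompose
from ctsbss.eval_sim import ScenarioSpec, generate_scenario, md_index

spec = ScenarioSpec("MIX", setting=1, T=2000, seed=42)
comp, sources, omega = generate_scenario(spec)

dec = decompose(comp, method="nss_sobi_gfobi", K=6,
                lags1=range(0, 7), lags2=range(0, 7), scheme="maxnorm")
print(dec.summary())
print("MD index vs ground truth:",
      round(md_index(dec.unmixing, omega).value, 3))
```

```
Compositional BSS decomposition
===============================
Method:          nss_sobi_gfobi
Observations:    2000
Components:      4
Parts:           5 (basis: pivot)
  lags1          (0, 1, 2, 3, 4, 5, 6)
  lags2          (0, 1, 2, 3, 4, 5, 6)
  K              6
  scheme         maxnorm
Objective:       150.095

clr loadings (sources x parts):
    part_1  part_2  part_3  part_4  part_5
z1 -0.0065  0.8671 -0.2965 -0.2832 -0.2809
z2  0.8930 -0.2306 -0.1904 -0.2102 -0.2618
z3 -0.0524  0.0733  0.8101 -0.4443 -0.3867
z4 -0.0238  0.0106  0.0289  0.6983 -0.7140

MD index vs ground truth: 0.069
```

Each row of the clr loading table shows how a recovered source weights
the original parts (rows sum to zero: only ratios matter).  The minimum
distance (MD) index measures how far Γ̂Ω is from a scaled permutation —
0 is perfect separation, values near 1 mean no information; 0.069 here
means the four latent series were recovered almost exactly.
`dec.sources` holds the source series, `dec.reconstruct(components=[0])`
maps any subset back to closed compositions, and
`CompositionalBSS(data, ...)` / `.fit()` expose the same functionality as
a model/results pair with `plot_sources()` and `plot_loadings()`.

A command-line interface mirrors the library:

```sh
ctsbss simulate --scenario MIX --T 2000 --seed 1 --out data.csv
ctsbss decompose --input data.csv --method nss-sobi-gfobi --K 6 \
    --lags1 0..6 --lags2 0..6 --weights maxnorm --out outdir/
ctsbss benchmark --reps 200 --setting 1 --out table.csv
```

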