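# Methods

This note records the statistical model implemented by `jointfm`, the
choices made where the design was genuinely open, and what the built-in
simulation study does and does not demonstrate.

## 1. Model

### Longitudinal submodel

For progeny *i* = 1,…,n measured at occasions *t* = 1,…,T and carrying QTL
genotype *j* ∈ {1 (QQ), 2 (qq)}:

    y_i(t) = u_j(t) + r_i(t) + e_i(t)

* `u_j(t) = β_j0 + β_j1 t + … + β_jr t^r` — genotype mean curve.
* `r_i(t) = θ_i0 + θ_i1 t + … + θ_im t^m`, θ_i ~ MVN(0, σ² I_{m+1}) —
  subject random curve, independent of the residuals.
* e_i ~ MVN(0, Σ), the same Σ for both genotypes.

Σ is modeled through its modified Cholesky decomposition M Σ Mᵀ = D.
Reading Σ as the covariance of an autoregression
y(t) = Σ_{t′<t} φ_{t,t′} y(t′) + ε(t), M is unit lower triangular with
−φ_{t,t′} below the diagonal and D = diag(σ²(t)) holds the innovation
variances.  Both are polynomial-regressed:

    φ_{t,t′} = δ_0 + δ_1 (t−t′) + … + δ_h (t−t′)^h
    log σ²(t) = η_0 + η_1 t + … + η_g t^g

Any finite (η, δ) yields a symmetric positive-definite Σ: the Cholesky
factor of Σ is exactly M⁻¹D^{1/2} (lower triangular, positive diagonal),
which the code obtains by a triangular solve — M is never inverted, and Σ
itself is only formed when a caller asks for it.  Classical AR(1)
(σ²ρ^{|t−t′|}) and compound-symmetry structures are provided for
comparison fits; they are parameterized as (log σ², atanh ρ) and share the
η/δ update machinery (one parameter per block).

Measurement occasions are coded t = 1,…,T in every polynomial; calendar
times are metadata.  Missing longitudinal values are not supported (the
intended designs have complete series).

### Event submodel

Each progeny has one observed event time s_i (no censoring).  The hazard is

    λ_i(t) = λ_0(t) · exp(γ μ_ij(t)),

with μ_ij(t) the subject's full modeled mean (genotype curve **plus** the
subject random curve — the hazard is defined conditional on θ_i), and λ_0
a step function with K equal-width intervals on [0, max s_i] (K = 5 by
default).  The trait–event link γ carries the biological coupling; γ = 0
separates the two submodels exactly, which the likelihood code preserves
(the event factor is then free of all longitudinal parameters).

The cumulative hazard ∫ λ_0(u) e^{γμ(u)} du has no closed form for
polynomial μ; it is computed by a composite trapezoid rule with 64
sub-segments per baseline interval (configurable; the heavy simulation
fits in the test suite use 16, where the rule is accurate to ~10⁻³
relative).  The rule converges at the expected h² rate; one consequence of
using the *same* rule in the event-time generator and the likelihood is
that simulated data and fitted model agree exactly, not just up to
quadrature error.  Integration is cut exactly at s_i (a partial trapezoid
on the last segment); events exactly on a knot belong to the interval to
their left.

### QTL mixture

For a putative QTL at D* cM from the first marker of a group, the
conditional genotype probabilities ω_{j|i} given the two flanking markers
follow from the recombination fractions r = ½(1 − e^{−2d}) (Haldane, d in
Morgans; map files store cM and are divided by 100).  Under no
interference the joint probability factorizes over the two sub-intervals,
so the table for observed flanks (a, b) is proportional to t₁(a)·t₂(b)
with t(match) = 1−r, t(mismatch) = r, normalized per row.  For selfed RILs
every two-point fraction is first transformed to R = 2r/(1+2r)
(recombination accumulated over generations of selfing); RIL data have two
homozygous classes, structurally matching the two-genotype mixture.  A
progeny missing one flank conditions on the other alone; missing both
falls back to (½, ½).  A QTL exactly on a marker belongs to the interval
on its left.

The joint likelihood is ∏_i Σ_j ω_{j|i} · f(y_i | Q_i=j, θ_i) ·
λ_i(s_i) e^{−Λ_i(s_i)}, computed in log space with log-sum-exp.

## 2. Priors

Defaults follow the soybean application that motivated the model:
β_j ~ MVN(0, 100·I) independently per genotype; σ² ~ IG(3, 1) (mean 0.5,
variance 0.25); γ ~ U(−3.0, −0.1); D* ~ U(0, D_m); λ_0k ~ Gamma(0.04, 1.0)
iid; η ~ MVN(0, 30·I); δ ~ MVN(0, 20·I).  All are configurable.

## 3. Sampler

A systematic scan: β → (recentering) → θ, σ² → η → δ → γ → λ₀ → D* → Q.

* **β_j, η, δ, γ, θ_i** — random-walk MH.  θ is proposed for all subjects
  at once and accepted subject-wise (the θ_i conditionals are independent
  given the rest).  Proposals landing outside the γ prior support, or at
  covariance parameters whose variances would overflow, are rejected.
* **Recentering move.** The mean and random-effect bases share their
  leading columns, so β_j and the θ_i of that genotype's subjects are
  strongly coupled along a likelihood-invariant direction.  An extra MH
  move shifts β_j by δ and subtracts δ from those θ_i: every subject mean
  is unchanged, the move is accepted on the prior ratio alone, and it is
  what lets β mix at the rate the θ-prior (which identifies β) allows.
  Without it the β chains crawl along the ridge.
* **σ²** — conjugate inverse-gamma Gibbs given θ:
  IG(α₁ + n(m+1)/2, α₂ + Σ‖θ_i‖²/2).  A log-normal MH mode is retained
  (`sigma2_update="mh"`).
* **λ_0k** — conjugate gamma Gibbs: Gamma(a + d_k, b + E_k) with d_k the
  events in interval k and E_k = Σ_i ∫_{interval k ∩ [0,s_i]} e^{γμ_i(u)} du
  (same quadrature); with γ = 0 this is the textbook piecewise-exponential
  posterior.
* **D\*** — MH with a uniform window proposal on
  (max(0, D*−ψ), min(D*+ψ, D_m)), ψ = 5 cM by default; the Hastings
  correction is the ratio of the two window widths.  The target involves
  only ∏_i ω_{Q_i|i}(D*) and the uniform prior.
* **Q_i** — exact two-cell Gibbs, probabilities ∝ ω_{j|i} e^{loglik_ij},
  normalized in log space.

Proposal scales adapt by Robbins–Monro on the log scale toward the
0.25–0.40 acceptance band **during burn-in only**, then freeze, preserving
the Markov property of the kept chain.  Chains are bit-reproducible given
a seed.

**Initialization.** Q is drawn from ω at a starting D* placed at the
midpoint of the marker interval containing the group midpoint (never
exactly on a marker, so ω is never a 0/1 indicator); β is then fitted by
genotype-wise least squares with three rounds of k-means-style
reassignment of Q; η comes from regressing the log sample variances on
the time basis; δ = 0; γ at the middle of its prior support; θ = 0; λ_0k
from matching counts to exposures.  The genotype-wise start matters: with
informative markers the likelihood around the separated solution is tight,
and a pooled start leaves the sampler a long ridge walk.

**Correctness evidence.** Each block is tested against its grid-integrated
or closed-form conditional, and the whole sampler passes a Geweke
successive-conditional test (prior-predictive draws vs. the chain that
alternates posterior updates with data re-simulation) on a small
configuration — the strictest practical check that all blocks target the
joint posterior.

**Likelihood tempering.** Every block accepts a temperature in [0, 1]
multiplying the likelihood (conjugate updates use tempered counts and
exposures), for power-posterior evidence estimation.

## 4. QTL detection

The Bayes factor BF = P(Y,S | no QTL) / P(Y,S | one QTL), where "no QTL"
means β₁ = β₂ for the group, is read on Jeffreys-style thresholds: BF < 1
evidence for a QTL, BF > 10 evidence for none.

**Default estimator — generalized Savage–Dickey.** The null is nested:
rotate to ψ = (β₂−β₁)/√2 and φ = (β₁+β₂)/√2.  A priori ψ, φ are
independent MVN(0, V) under the alternative (V = 100·I), and the null is
the slice ψ = 0 with φ ~ MVN(0, 2V).  Then

    BF = [ p(ψ=0 | data) / π(ψ=0) ] · E[ N(φ; 0, 2V) / N(φ; 0, V) | data ]

The posterior density of ψ at 0 is evaluated from a Gaussian fit to the
alternative chain (the ψ posterior here is unimodal and tight); the O(1)
correction term is averaged over the chain's φ draws via log-sum-exp.
One full-temperature chain per group suffices.

**Why not thermodynamic integration by default.** The power-posterior
path is implemented (descending ladder t_j = ((j+1)/J)⁵ warm-started from
the full-temperature fit, trapezoid combination, spectral standard
errors) and is validated against a closed-form evidence on a conjugate
toy model.  But under the very diffuse covariance priors the near-prior
expectation of the log likelihood is astronomically negative (the
log-variance polynomial exponentiates prior draws), so the ladder must
start above t = 0 — the omitted common segment cancels only in the
ratio — and the difference of two independently estimated marginal
likelihoods retains a standard deviation of tens of log units at desk
scale, swamping the null-data signal (≈ +17 log units here).  Measured on
null-simulated data, the Savage–Dickey estimator gives log BF = 16.8 ± 1.7
across seeds where the tempered-ladder difference scatters by ± 30.  The
estimator name is recorded in every `BFResult`.  The harmonic-mean
estimator is included for comparison only (its instability is
documented at the call site).

## 5. Order selection, PPC, heritability, diagnostics

* **BIC.** For each (r, m, g, h) on the order grid (orders 2–3), the
  genotype-agnostic marginal likelihood — y_i ~ MVN(X_r β, Σ + σ²X_m X_mᵀ)
  with β profiled out by GLS — is maximized over (η, δ, log σ²) by
  L-BFGS-B; BIC = −2·loglik + p·log n with p = (r+1)+(g+1)+(h+1)+1.  The
  random-curve order m enters the fit through X_m but not the parameter
  count (σ² is a single scalar regardless of m); selection is used for its
  *ranking*.  Convergence is flagged per tuple.
* **Posterior predictive BF.** For each of m posterior draws, a replicate
  population is simulated from the likelihood at that draw (new θ, Q, y, s
  on the fitted baseline partition) and the BF analysis is re-run at
  reduced settings; failures are counted and excluded.
* **Heritability.** H² compares the variance (across progeny, averaged
  over the grid) of each subject's posterior-expected genotype mean value
  with total phenotypic variance; the per-QTL variance explained weights
  the squared deviation of the two genotype mean curves by the posterior
  genotype frequencies.  Both are conventions — the exact decomposition is
  a modeling choice, stated here so the numbers are interpretable.
* **Diagnostics.** Geweke z-scores (first 10% vs last 50%,
  Bartlett-windowed spectral density at zero frequency) and the
  Brooks–Gelman multivariate potential scale reduction factor across
  chains, MPSRF = (S−1)/S + (m+1)/m · λ_max(W⁻¹B/n) → 1 under convergence.

## 6. The simulation study (synthetic-data generator)

`SimulationDesign` defaults reproduce the validation design: 200 RIL
progeny; 11 evenly spaced markers on 100 cM; one QTL at 43 cM (between the
markers at 40 and 50 cM); T = 8 occasions; genotype truths
β₁ = (−1.1524, 2.6829, 0.2295), β₂ = (−3.1004, 5.3250, −0.0250) — the
detected group-20 QTL estimates reused as generating values.  Marker and
QTL genotypes arise from a sequential Markov walk along the chromosome
with RIL-transformed Haldane two-point fractions.

The remaining truths are not fixed by any published table and are this
generator's conventions:

* **η = (−4.0, 0.1, 0.0), δ = (0.2, −0.05, 0.0), σ² = 0.001.**  The
  anchor is the precision the original study reports for its mean
  coefficients (Monte-Carlo SEs near 0.01, credible intervals of width
  ~0.07 at n≈200): residual sd ≈ 0.14–0.20 reproduces that regime.  With
  visually larger noise (residual sd ≈ 1.3) a single n=200 dataset carries
  sampling error of ±0.15–0.8 on the curve coefficients and no estimator
  could match the reported recovery precision.
* **γ = −0.5, λ_0k ≡ 2.0, K = 5 on [0, 8].**  The original study reused
  field-recorded event times that are not available, so events here come
  from the model itself by inverting the survival curve on the quadrature
  grid.  With the trait scale of the design (mean values up to ≈38) and
  γ = −0.5, events concentrate early in the window; a draw that would fall
  beyond the support is redrawn (conditioning on the window) rather than
  truncated — truncated times recorded at the last knot act as strong
  spurious evidence dragging γ to its prior boundary.

What passing recovery tests on these data do **not** show: robustness to
real measurement-error scales, to censored or mid-season event times, to
segregation distortion or missing markers, or to model misspecification of
the mean polynomial — the generator draws from exactly the fitted model
class (by design: it validates the estimation machinery, not the model).
The covariance-structure comparison (unstructured vs AR(1)/CS fits on
unstructured-generated data) is likewise gentler here than with noisy
field data, because near-certain genotype classification leaves little for
the covariance model to influence; the interval-width ordering is the
robust signature at this noise scale.

## 7. Problem sizes used in the shipped checks

The test suite and the reproduction script run the full n = 200 design
with 30,000 kept + 5,000 burn-in iterations (thin 5) for parameter
recovery, ten n = 100 populations per Bayes-factor direction check
(2,500-iteration chains), five seeds × three covariance structures
(6,000-iteration chains) for the localization comparison, and ten n = 184
replicates for BIC order selection — sizes chosen so the whole suite runs
in minutes on one core while keeping every check's Monte-Carlo error well
inside its decision margin.  The original analysis scale (120,000
iterations) is available by passing the corresponding `iterations` and
`burn_in`.

## 8. Known limitations

* Two genotype classes only (RIL/backcross); no F₂ three-genotype tables,
  no multipoint (HMM) genotype probabilities, no map estimation.
* One QTL per linkage group; no epistasis or multi-QTL search.
* No censoring in the event submodel; one event per progeny.
* Complete longitudinal series on a common grid (per-subject grids are
  supported by the design-matrix layer but untested beyond that).
* The Savage–Dickey density evaluation assumes a well-behaved (unimodal,
  approximately Gaussian) posterior for the genotype contrast; with very
  weak data it would inherit the usual density-estimation error.
* Heidelberger–Welch stationarity testing is not implemented; Geweke and
  MPSRF are.
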