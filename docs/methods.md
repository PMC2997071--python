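# Methods

## Model

A Lévy process `L` is characterised by its exponent `ψ` through
`E[exp(iξ L_h)] = exp(−h ψ(ξ))`.  We fix this sign convention throughout,
so every valid exponent satisfies `ψ(0) = 0`, `Re ψ ≥ 0` and Hermitian
symmetry `ψ(−ξ) = conj(ψ(ξ))`.  A Feller (Lévy-type) process is described
by a state-indexed family of exponents `ψ_x`: at state `x` it moves, over a
short time, like the Lévy process with exponent `ψ_x`.

### Component exponents and samplers

| component | exponent ψ(ξ) | increment law at h | sampler |
|---|---|---|---|
| Brownian(drift, σ) | −i·drift·ξ + σ²ξ²/2 | N(drift·h, σ²h) | Gaussian |
| Poisson(λ) | λ(1 − e^{iξ}) | Poisson(λh) | Poisson counts |
| stable(α, c), 0<α≤2 | (c\|ξ\|)^α | h^{1/α}·c·S_α | Chambers–Mallows–Stuck |
| Gamma(a, b) | a·Log(1 − iξ/b) | Gamma(ah, rate b) | Gamma |
| NIG(α, β, δ, μ) | −iμξ + δ(√(α²−(β+iξ)²) − √(α²−β²)) | NIG(α, β, δh, μh) | IG variance–mean mixture |
| Meixner(a, b, d, m) | −imξ + 2d·Log(cosh((aξ−ib)/2)/cos(b/2)) | Meixner(a, b, dh, mh) | grid inverse-CDF |

Notes on the less standard choices:

* **Stable.**  `S_α` is standard symmetric α-stable (CF `exp(−|ξ|^α)`),
  drawn by the Chambers–Mallows–Stuck transform for α ∉ {1, 2}, by a direct
  Cauchy inversion at α = 1 and as N(0, 2) at α = 2.  Mind the α = 2
  convention: ψ(ξ) = c²ξ² corresponds to a Gaussian with variance `2c²h`,
  twice the Brownian parameterisation.  The sampler is cross-checked in the
  tests against `scipy.stats.levy_stable` as an independent oracle.
* **NIG.**  The mixing law was not trusted from memory: with
  γ = √(α²−β²), `Z ~ InverseGaussian(mean δh/γ, shape (δh)²)` and
  `X = μh + βZ + √Z·N(0,1)` was validated against the exponent via the CF
  diagnostic (a parameterisation error here shows up immediately as a CF
  mismatch).
* **Meixner.**  No exact transform sampler exists; we tabulate the density
  `f(y) ∝ e^{by/a} |Γ(dh + iy/a)|²` (complex log-gamma from
  `scipy.special.loggamma`), on a grid centred at the mean `a·dh·tan(b/2)`
  and extended until the density falls below 10⁻¹² of its mode (the tails
  decay exponentially at rate (π ∓ b)/a, so the range is finite and small).
  The grid has at least 2¹² points, refined so the spacing is at most
  σ/64 (capped at 2¹⁸ points); the trapezoid mass must equal 1 within
  10⁻⁶ or the sampler raises a numerical error with the grid diagnostics
  attached.  Draws are linear interpolation of the inverse CDF.
* **Branches.**  All complex logs and square roots are principal branches.
  For |b| < π the Meixner log argument has strictly positive real part and
  the NIG root argument has positive real part, so no branch tracking is
  needed on the diagnostic grids (kept within |ξ| ≤ 100).

### Families

**Region mixtures.**  Disjoint closed intervals with uniform separation
ε > 0 get mollified-indicator mixers `φ_i(x) = max(0, 1 − d(x, R_i)/ε)`:
1 on the region, 0 at distance ≥ ε, Lipschitz constant 1/ε.  The mixed
exponent is `ψ_x = Σ φ_i(x) ψ_i` and, because independent exponents add,
`Z_x(h) =(d) Σ_i L_i(φ_i(x)·h)` — the mixture sampler is exact, drawing
each active component for its weighted time (zero-weight components are
skipped and consume no randomness).  When adjacent gaps have width exactly
ε the ramps form a partition of unity on the gaps; in general the
construction requires `Σ_i φ_i(x) > 0` everywhere (otherwise the process
would freeze), which is screened on a dense grid at build time and
reported with the offending state.

**Parameter fields.**  One component kind with state-dependent parameters.
Admissibility is screened at construction on a grid over x ∈ [−50, 50]
(10⁴ points): the stable index must stay in a user-declared
`[α_lo, α_hi] ⊂ (0, 2)`; the NIG asymmetry must satisfy
`|β(x)| ≤ α(x) − ε₀` (default ε₀ = 0.5); the Meixner parameters must obey
`a(x) ≥ ε₀`, `|b(x)| ≤ π − ε₀`, `d(x) ≥ ε₀` (default ε₀ = 0.05).  The
screen is sampled, not a proof — adversarial user functions that violate a
constraint only between grid points or outside [−50, 50] can evade it; the
built-in defaults cannot.  Likewise the Lipschitz check on mixing
functions is a finite-difference bound.

### Default example families

The four registry models are qualitative stand-ins chosen to reproduce the
described behaviours; each functional form is a package choice:

* `bpc` — Brownian(0, 1) on (−∞, −6], Poisson(1) on [−5, 5],
  Cauchy (stable α = 1, scale 1) on [6, ∞), ε = 1.  The gap width 1 is the
  natural reading of the ±5/±6 geometry and makes Σφ ≡ 1.
* `stable_like` — α(x) = 1.5 + 0.49·tri(x), tri the unit triangle wave of
  period 2π: Lipschitz but not smooth, oscillating over [1.01, 1.99],
  bounded away from 0 and 2.
* `nig_like` — α = 2, δ = 1, μ = 0, β(x) = −tanh(x).  The mean of the NIG
  law has the sign of β, so the increment law is skewed back towards the
  origin from either side: mean reversion produced by asymmetry, not by a
  drift term.
* `meixner_like` — b = 0, d = 1, m = 0, a(x) = 0.5 + 1.5·e^{−x²/8}.  The
  density's exponential tail-decay rate is (π ∓ b)/a, so a larger `a` near
  the origin means slower decay and bigger steps there.

## Path scheme

`x_{k+1} = x_k + z_k` with `z_k` one draw of `Z_{x_k}(h)`, for
K = floor(T/h) steps (no partial final step: a fractional step would change
the increment law).  Values exist at grid times only; plots render the
càdlàg step-function convention.  Weak convergence as h → 0 holds when the
family satisfies the growth bound `sup_x |ψ_x(ξ)| ≤ C(1 + ξ²)` — estimated
on a grid by `exponent_growth_bound`; it is 1/2 for unit Brownian, ≤ 2λ
for Poisson(λ) — and when the process is unique for its restricted
generator, which cannot be checked numerically and is assumed.  For a
state-independent family the scheme is exact in law at every grid time
regardless of h, which the tests exploit as a strong end-to-end check.

Reproducibility: path j draws its increments in step order from the
`SeedSequence` substream of the root seed keyed `(j,)`, so ensembles are
bit-reproducible and a path does not depend on how many other paths are
generated.  The weak-convergence probe keys its substreams by
`(h-index, path)`.

## Diagnostics

* **CF distance** — `max_ξ |ECF_n(ξ) − exp(−h ψ_x(ξ))|` on 21 equispaced
  points in [−5, 5].  Under the null the deviation is O(1/√n) uniformly on
  the grid; the package-wide acceptance bound is 5/√n (0.016 at n = 10⁵).
* **Moment oracle** — mean and variance from central finite differences of
  `exp(−hψ)` at ξ = 0 with step 10⁻⁴ (truncation error O(ε²·|φ⁗|) ≈ 10⁻⁸
  for the built-in laws, negligible against Monte Carlo error); agrees with
  the closed forms for Brownian, Poisson and Gamma to 10⁻⁶ relative.
  Infinite-variance laws (stable α < 2, and mixtures that are stable at the
  probe state) are rejected with an unsupported-law error.
* **Goodness of fit** — one-sample KS for normal/Cauchy/Gamma references,
  Pearson χ² with expected-count-≥-5 tail-merged bins for Poisson; all
  pass/fail wrapping in the tests uses level 0.01 with fixed seeds.
* **Skewness SE** — symmetry checks use the delta-method standard error
  `√((μ₆/σ⁶ − 6μ₄/σ⁴ + 9)/n)` valid under a symmetric null; the Gaussian
  `√(6/n)` would understate the error for the leptokurtic NIG/Meixner laws.

## Problem sizes

The test suite and the acceptance script use n = 10⁵ draws for CF and
moment checks, n = 10⁴ for KS/χ² region tests, 10³ paths for terminal-law
comparisons (T = 1, h = 0.01) and 2000 paths for the weak-convergence probe
on `bpc` (T = 1, h ∈ {0.2, 0.1, 0.05}, f = identity clamped to [−20, 20]).
These sizes give Monte Carlo resolution comfortably inside every asserted
band while keeping a full run to seconds.

## Limitations

* One-dimensional processes only; no Lévy–Khintchine triplets or
  user-supplied exponents as inputs (the component registry is the
  extension point); no tempered-stable/CGMY components.
* The simulator provides evidence of weak convergence, not proof; strong
  (pathwise) error rates and the SDE representation of the scheme are out
  of scope.
* Constraint screening is grid-sampled (see above).
* Families with state-dependent killing or time inhomogeneity are not
  representable.
* Passing diagnostics certify the increment laws and the scheme's
  mechanics under the package's own default conditions; they do not
  validate any particular empirical system's fit to these models.
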