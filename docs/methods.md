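# Methods

## Model and estimation procedure

The package targets one-dimensional stationary Markov processes of
jump-diffusion type,

    dX_t = a(X_t) dt + b(X_t) dW_t + ξ dJ_t,

with Wiener process W, Poisson process J of rate λ, and state-independent
Gaussian jump amplitudes ξ ~ N(0, s) (s is the amplitude *variance*). Its
transition density obeys the Kramers–Moyal (KM) equation, whose operator
L = Σ_p (−∂/∂x)^p D_p(x) carries coefficients of all orders; the
Fokker–Planck equation is the truncation D_p ≡ 0 for p > 2.

Estimation proceeds in three steps:

1. **Conditional moments.** For lag ℓ (default 1) and τ = ℓ·Δt, the per-bin
   moment M_n(x, τ) is the average of (X_{t+ℓ} − X_t)^n over all samples
   with X_t in the bin. Analysing the smallest available lag is the best
   case; larger lags are supported for diagnostics only.
2. **Finite-time inversion.** Exponentiating the KM operator and expanding
   the exponential as a power series makes M_n an exact polynomial in τ and
   D_1…D_n — a partial *ordinary* Bell polynomial series — once all terms
   containing spatial derivatives of the coefficients (the Φ terms) are
   dropped. The reciprocal relation of the partial *exponential* Bell
   polynomials inverts this exactly; it is identical to the
   moment → cumulant transformation, i.e. n!·τ·D_n is the n-th cumulant of
   the increment law. Truncating the forward series at τ^m before
   inverting recursively defines the order-m approximation: order 1 is the
   naive M_n/(n!τ), order n ("full") the complete correction. D_1 needs no
   correction, and for D_2 order 2 and full order coincide.
3. **Parameter recovery.** For the constant-coefficient process the even
   coefficients obey D_2 = (b² + sλ)/2 and D_{2n} = s^n λ/(2^n n!)
   (from ⟨ξ^{2n}⟩ = (2n)!/(2^n n!)·s^n), giving s = 6·D̄_6/D̄_4,
   λ = 8·D̄_4/ŝ², b² = 2·D̄_2 − ŝλ̂, with D̄_n the occupancy-weighted
   average over a central state window. The drift slope is a weighted
   least-squares fit of D_1(x) against x.

### Assumptions

- The series is Markovian, stationary, uniformly sampled, and scalar.
- Jumps are compound Poisson with Gaussian amplitudes; amplitude and rate
  are state-independent (this is what justifies averaging D_4 and D_6 over
  bins before taking ratios).
- The Φ (derivative) terms are neglected in estimation, exactly as in the
  closed-form inversion. The operator expansion that *does* generate them
  (`expand_with_derivatives`) exists for verification and diagnostics: its
  zero-derivative part reduces term-for-term to the truncated Bell series,
  every term satisfies the bookkeeping rule (sum of subscripts minus sum of
  derivative orders equals the moment order), and its second-order
  derivative part matches the closed form
  Φ_n^[2] = (τ²/2) Σ_{s<n} Σ_{m>s} n!·C(m,s)·D_{n−s}^{(m−s)}·D_m.

## Exact arithmetic and the derivative expansion

Bell coefficients and all symbolic expansions use exact integer/rational
arithmetic (`fractions.Fraction`); the Bell evaluators are generic over any
commutative ring, so the same code serves sympy symbols, floats, and
per-bin numpy arrays. Partition enumeration is canonical (lexicographically
descending on multiplicities) so symbolic output is reproducible; monomials
are ordered by τ power, then descending on the exponent vector.

`expand_with_derivatives` applies the adjoint operator Σ_p D_p ∂^p k-fold
to (x − x′)^n and evaluates at x = x′, which is integration by parts done
once and for all. Sums over the operator index are truncated at
`truncation_N` and derivative orders at `max_deriv`, both explicit
parameters; exceeding the cap sets a truncation flag on the result. For the
Fokker–Planck truncation the third-order derivative terms for M_1 and M_2
carry the expected τ³/6 and τ³/3 prefactor structure; the expansion shows
that the final third-order M_1 term is D_1^{(4)}·D_2·D_2 — the unique
completion consistent with the bookkeeping rule — and the tests pin the
full lists down term by term.

## Simulator

Euler–Maruyama with the sampling step as integration step by default:
X_{k+1} = X_k + a(X_k)Δt + b(X_k)√Δt·G_k + Σ_{i≤K_k} ξ_i, with
K_k ~ Poisson(λΔt) — exact compound-Poisson increments at any λΔt, not the
single-jump Bernoulli approximation. An optional `refine` factor integrates
at Δt/refine and down-samples. One user seed spawns three independent
sub-streams (Brownian, Poisson counts, amplitudes) via
`numpy.random.SeedSequence`, so the diffusion path is unchanged when the
jump channel is switched off and trajectories do not depend on draw
interleaving. For linear drift and constant diffusion the recursion is
solved vectorised with an IIR filter; general callables fall back to an
explicit loop.

## Defaults and tunables

| parameter | default | meaning / rationale |
|---|---|---|
| bins | 30 equal-width over mean ± 4 sd | balances bin occupancy against drift curvature across the occupied range |
| min_count | 100 transitions | sixth moments in sparser bins are noise-dominated; sparse bins are flagged and excluded, never dropped from files |
| lag | 1 | smallest temporal difference is the least biased |
| estimator | histogram | Nadaraya–Watson/Epanechnikov optional; Silverman's-rule bandwidth |
| fit window | \|x − μ\| ≤ 2σ | jump terms are state-independent, so the central, well-populated window is averaged (occupancy-weighted) |
| jump test | D̄₄ > 3 × SE | SE by batch means over 20 contiguous segments |
| error method | batch means (20 segments) | a moving-block bootstrap (200 replicates) is implemented but costs ~10× more pipeline passes for comparable scale; batch means is the default |

Negative full-order D₂/D₄ in a bin (possible from sampling noise) is
reported as-is with a warning flag, never clipped. Non-positive averaged
D̄₄ or D̄₆ suppresses jump inference: s and λ are reported as NaN with a
flag and b² absorbs the whole of 2·D̄₂.

## Synthetic data and what the tests show

The generator emulates the two study conditions used throughout: an
Ornstein–Uhlenbeck process (a = 1.0, b = 0.5) and a Poissonian
jump-diffusion (a = 0.5, b = 0.5, s = 0.75, λ = 0.6). The sampling interval
is a free parameter: Δt = 0.1 exhibits the finite-time artefacts the
correction removes, Δt = 0.01 is the regime where quantitative jump
recovery is asserted, since the KM description of discontinuous processes
is itself only exact as Δt → 0 and a residual bias at coarse Δt is expected
regardless of correction order. Simulation studies use 5×10⁶ steps, which
keeps the full suite within a few minutes while leaving the Monte-Carlo
error of the recovered parameters at the few-percent level.

What passing tests show: unbiasedness and consistency of the pipeline on
exactly-Markovian, exactly-uniformly-sampled synthetic data with Gaussian
jump amplitudes. What they do not show: robustness to measurement noise,
memory effects (a Markov test such as Chapman–Kolmogorov is out of scope
and should precede any real-data analysis), state-dependent jump rates or
amplitudes, or non-Gaussian jump laws.

## Numerical notes and limitations

- The numeric inversion is a triangular recursion in double precision; the
  round trip through exact forward moments recovers coefficients to ~1e−10
  relative error at the orders used here.
- Constant (zero-variance) series are binned over a unit-wide fallback
  window rather than raising.
- Ratios 6·D̄₆/D̄₄ amplify relative errors of the sixth moment, the noisiest
  quantity in the pipeline; λ̂ inherits error from ŝ quadratically. Rate
  and amplitude enter D_{2n} only through s^n λ, so very small λ with large
  s is indistinguishable from the reverse at fixed D₄ without D₆.
- Files are plain text with `%.17g` floats, so write → read → write is
  byte-identical.
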