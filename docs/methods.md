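# Methods

## Model and control

The package analyses the delayed blowflies model
`x'(t) = a x(t-τ) e^{-b x(t-τ)} - c x(t)` under hybrid control. In
scaled time (`u(t) = x(τt)`, delay normalized to 1) the controlled
equation is

```
u'(t) = α [ aτ u(t-1) e^{-b u(t-1)} - cτ u(t) ] + (1-α) τ (u(t-1) - u*),
```

with gain `α ∈ (0,1]` (α = 1 is the uncontrolled system). The
equilibrium `u* = (1/b) ln(a/c)` is unchanged by the control; all
analyses work in the deviation coordinate `v = u - u*` and assume
`a > c > 0`, `b > 0`.

### Parameters

| parameter | meaning | unit | default (worked example) |
|---|---|---|---|
| a | max per-capita daily egg production | 1/day | 30 |
| b | inverse size at maximal reproduction | 1/size | 2 |
| c | per-capita daily death rate | 1/day | 2 |
| α | hybrid-control gain | — | {1, 0.9, 0.6} |
| τ | delay (bifurcation parameter) | day | scanned |
| h = 1/m | step-size in scaled time | — | {1, 1/2} |
| η | constant initial deviation | size | 0.1 |

The defaults are the published worked-example values; they put
`b u* = ln(a/c) ≈ 2.708` above the uncontrolled stability threshold 2,
so the uncontrolled model bifurcates at a finite delay and the control
question is non-trivial.

## Continuous Hopf analysis

Linearization gives the transcendental characteristic equation
`λ = αcτ[(1-bu*)e^{-λ} - 1] + (1-α)τ e^{-λ}`. With
`β = αc(1-bu*) + (1-α)`, a purely imaginary root `λ = iθ` requires
`β cos θ = αc` and `β sin θ = -θ/τ`, hence `θ = τ·rate` with
`rate = √(β² - (αc)²)`; a crossing exists iff
`b u* > 2 + (1-α)/(αc)` (which makes β < -αc < 0 and the radicand
positive). The crossing angle θ₀ is resolved quadrant-correctly by
`atan2(-rate/β, αc/β)` and lies in (π/2, π); the critical delays are
`τ_k = (θ₀ + 2kπ)/rate`, exactly spaced by 2π/rate.

The transversality speed is obtained by implicit differentiation of the
characteristic equation and imposing the crossing conditions:

```
d(Re λ)/dτ |_{τ_k} = τ_k (β² - (αc)²) / Δ,
Δ = [1 + τ_k β cos θ₀]² + [τ_k β sin θ₀]².
```

This closed form is validated in the tests against a two-sided finite
difference (step 1e-5) of the root tracked across τ_k by damped complex
Newton iteration seeded at iθ₀; agreement is ~1e-6 relative. It is
strictly positive whenever a crossing exists, so each τ_k is a genuine
Hopf point.

## Discretizations

Both schemes use step `h = 1/m` so the unit delay spans exactly m
steps. The NSFD scheme replaces the denominator h of the forward
difference by `ψ(h) = (1 - e^{-αcτh})/(αcτ) = h + O(h²)`, chosen so the
linear decay subproblem `v' = -αcτ v` is solved *exactly* (verified to
machine precision over thousands of steps). The Euler scheme uses the
plain forward rule. `v = 0` is a fixed point of both maps for all
parameters — a consequence of the equilibrium identity `c = a e^{-bu*}`
— and the step implementations are checked against independent
term-by-term transcriptions of the update formulas to 1e-14.

Simulations start from a constant history `v ≡ η` on the delay
interval (η = 0.1 by default; the qualitative verdicts are insensitive
to small η). A trajectory is classified from the last 10% of its steps:
`converges` if max |v| < 1e-3, `oscillates` if > 1e-2, `indeterminate`
between, `diverges` if any iterate exceeds 1e6 in magnitude (the
recruitment exponential overflows loudly rather than silently for very
negative v, raising a divergence signal). Default run length is 4000
steps, ample for the printed parameter sets.

## Neimark–Sacker detection

The linearized NSFD map has the trinomial characteristic polynomial
`λ^{m+1} - ã₀λ^m - ã₁` with `ã₀ = e^{-αcτh}`,
`ã₁ = (1-e^{-αcτh})(1 + (1-α)/(αc) - bu*)`. The Euler counterpart,
`ã₀ = 1 - αcτh`, `ã₁ = τh[αc(1-bu*) + (1-α)]`, is derived by
linearizing the Euler update and validated against a finite-difference
Jacobian of the step function. Roots are computed as eigenvalues of the
(m+1)×(m+1) companion matrix — well conditioned for the m used here —
and a multiprecision polynomial solver serves as an independent test
oracle.

`critical_tau` scans τ from 1e-6 upward in steps of 0.01 for the first
sign change of `spectral_radius(τ) - 1` and bisects to tolerance
(default 1e-8; 1e-12 where eigen-residual tests need it). The scan
cannot start at τ = 0, where the polynomial degenerately carries the
root λ = 1. The crossing eigenvalue is verified to be a genuine complex
pair (a real crossing raises "flip crossing" — outside the theory);
its argument ω₀ matches the closed-form cosine condition

```
cos ω = 1 + (1-e^{-αcτh})² (bu* - L)(2 + L - bu*) / (2 e^{-αcτh}),  L = (1-α)/(αc),
```

whose right-hand side exceeds 1 throughout the stable-for-all-delays
regime — hence no crossing there (checked on a τ-grid to 10). That
guarantee is specific to the NSFD polynomial: the Euler polynomial does
leave the unit disc at large τ even in that regime (ã₀ < -1
eventually), one more sense in which the NSFD scheme is dynamically
consistent and Euler is not.

The discrete transversality uses the closed form

```
d(r²)/dτ = 2αch e^{-αcτh}(m+1+m e^{-αcτh})(1-cos ω)
           / { (1-e^{-αcτh}) [((m+1)cos ω - m e^{-αcτh})² + ((m+1)sin ω)²] },
```

positive for any step-size, and is cross-checked by finite differences
of the dominant-root modulus (agreement ~1e-4 relative or better). At
zero delay the departing unit root obeys
`d|λ|²/dτ = 2h(1 - α - bu*·αc) < 0`, so stability always holds for
small delays in the regimes of interest.

For h = 1 (m = 1) the crossing admits a closed form used as an oracle:
a complex pair on the unit circle has root product `-ã₁ = 1`, giving
`τ₀ = -ln(1 - 1/(bu* - 1 - L))/(αc)` for NSFD and
`τ₀ = 1/(αc(bu*-1) - (1-α))` for Euler; bisection agrees to 1e-8.

## Normal form

At τ₀ the right eigenvector is `q = (e^{imω₀}, ..., e^{iω₀}, 1)` and
the adjoint eigenvector `q* = conj(K)(1, ã₁e^{imω₀}, ..., ã₁e^{iω₀})`
with the normalization constant

```
K = [ e^{+imω₀} + m ã₁ e^{-iω₀} ]^{-1},
```

the unique scalar making `⟨q*, q⟩ = Σ conj(q*_i) q_i = 1` (direct
evaluation of the inner product fixes the sign of the first exponent;
the tests verify normalization to 1e-12 and both eigen-residuals to
1e-10). The quadratic/cubic Taylor coefficients of the map act only on
the delayed coordinate, `b̃ = (1-e^{-αcτ₀h})(b²u* - 2b)` and
`c̃ = (1-e^{-αcτ₀h})(3b² - b³u*)`; both are cross-checked against
Richardson-extrapolated central differences of the scalar NSFD update.
Note `3b² - b³u* = 12 - 8u* ≈ +1.168 > 0` at the worked-example
parameters. The bilinear extension `b₀(φ,ψ) = b̃ φ_m ψ_m` is forced by
symmetry of second derivatives.

The critical coefficient is assembled twice: from the general
projection formula (g₂₀, g₁₁, g₀₂, g₂₁ with the center-manifold
corrections w₂₀, w₁₁) and from the compact expression
`c₁ = (K/2)(b̃²/a(λ₀²) + 2b̃²/a(1) + c̃)` with
`a(λ) = λ^{m+1} - ã₀λ^m - ã₁`. The two agree to machine precision at
every computed crossing (this equivalence was confirmed numerically,
not assumed), and the tests pin the agreement at 1e-8. All divisions
are guarded by a 1e-10 resonance threshold: λ₀ too close to a low root
of unity raises an explicit error rather than returning an
ill-conditioned number. Classification: attracting invariant curve for
τ > τ₀ iff `Re[e^{-iω₀} c₁(τ₀)] < 0`; at the worked-example parameters
the indicator is negative for all three gains at h = 1/2
(supercritical), consistent with simulations just past τ₀ settling onto
bounded oscillations whose amplitude grows continuously from zero. The
normal form is implemented for the NSFD map only; the Euler map's
critical point is detected but not classified.

## Problem sizes and determinism

The bundled experiments use m ∈ {1, 2} (companion matrices of size 2-3,
the published grid), convergence studies up to m = 16, and simulations
of 4000-8000 steps; the full test suite and the acceptance script each
complete in seconds. Nothing in the method is stochastic: identical
inputs produce byte-identical CSV/JSON outputs, and the acceptance
script's `--seed` flag exists only for interface uniformity.

## Limitations

- The theory covered here is local: no global attractivity or
  oscillation theory of the original model, and no computation of the
  invariant curve's radius or rotation number.
- Strong resonances (λ₀ at a low root of unity) are detected and
  refused, not analysed.
- The region `b u* ≤ (1-α)/(αc)` and exact threshold hits carry no
  stability claim and are labelled `out_of_theory`.
- The trajectory verdicts are qualitative contracts (tail-amplitude
  thresholds), not reproductions of any particular published figure;
  initial data for those figures are not specified anywhere, so exact
  figure replication is out of scope.
- No adaptive stepping, no interpolation between grid points, and no
  general DDE integrator: the continuous model is analysed in closed
  form only.
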