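# Methods

## Model family

The package implements the two-mating-type gamete-competition game in
which gamete sizes *x*, *y* evolve under selection on

    w_x(x, y) = n(x) g(x) f(x, y),    w_y(x, y) = n(y) g(y) f(x, y).

Assumptions: very large panmictic population; two pre-existing mating
types with strictly disassortative fusion; haploid-style trait dynamics
with each type's gamete size evolving on its own axis; a fixed gametic
budget *M* per parent per season. Diploidy, more than two mating types,
assortative fusion, and explicit genetics (e.g. linkage of a size
modifier to the mating-type locus) are out of scope.

Component functions and their parameters (all sizes in the same
arbitrary mass units as *M*):

| quantity | form(s) | parameters | default |
|---|---|---|---|
| trade-off `n(x)` | `(M/x)^(1/k)` | `M > 0` budget, `k ≥ 1` inefficiency | `M=1`, `k=1` |
| gamete survival `g(x)` | `exp(−α/x)` or step at δ | `α ≥ 0` scale, `δ ∈ (0, M)` viability cutoff | `α=1`, `δ=1e−3` |
| zygote survival `f(x,y)` | `exp(−β/(x+y))` or `c(x+y)^h` | `β ≥ 0` scale; `c > 0`, `h > 0` | `β=2`, `c=1`, `h=1` |

`k` has a concrete biological reading: with `d` rounds of binary cell
division (`n = 2^d`), a fraction `1 − q = 1 − 2^(1−k)` of the remaining
resource is lost at each round, and `x = M q^d / 2^d` reproduces
`x = M/n^k` exactly (`reparametrise_tradeoff`). The power-law `f` is
deliberately left uncapped: eventual saturation of zygote survival is
not needed for any question the family answers.

Log fitness is the direct composition
`ln w = (1/k)(ln M − ln x) + ln g + ln f`. Selection gradients and the
Jacobian of the gradient system are closed-form per variant; finite
differences exist only in the test suite as an independent oracle,
because every result in this family hinges on exact gradient roots. The
equilibria are invariant to differentiating absolute instead of log
fitness (`dw/dx = w · d ln w/dx` with `w > 0`); log-gradients are used
throughout because they also give the correct *magnitude* of change for
the gradient dynamics.

A size below the viability cutoff in the threshold variant yields a
`−inf` log-fitness sentinel rather than an exception, so scans and
optimizers can treat inviability as an absorbing worst case; genuinely
malformed inputs (nonpositive sizes, unknown forms) raise typed errors.

### The budget cap

`M` enters log fitness only through the additive constant `ln(M)/k`, so
it cancels from every gradient and Hessian. Derivative evaluations
therefore accept any positive sizes, while the biological constraint
`x ≤ M` (a parent cannot make even one gamete larger than its budget)
is enforced where gamete *numbers* are computed (`gamete_number`,
fertilization counts) and as the upper bound of scan grids and
integration boxes. Callers working near the cap see it signalled, never
silently clamped, in core evaluations.

## Closed forms and the numerical oracle

For the exponential forms the equilibria are exact: isogamy at
`x = y = k(α + β/4)`; for `β ≥ 4α` an anisogamous pair with
`x + y = kβ` and sizes `(kβ/2)(1 ± √(1 − 4α/β))`. The stable branch is
isogamy below `β = 4α` and anisogamy above; both branches equal `2kα`
at the threshold, so the stable equilibrium is continuous there. The
quadratic's + and − roots are always reported as (macro, micro); which
mating type becomes the macrogamete is historical and is resolved only
by the dynamics module (initial asymmetry decides).

Every closed form is re-derived numerically by an independent route:
`solve_equilibrium` runs scipy's hybrid (Powell) root finder on the
gradient system in log-coordinates (so iterates stay positive), from a
deterministic multi-start set — the isogamous diagonal plus the two
asymmetric corners `(0.9M, 2δ)`, `(2δ, 0.9M)` — and accepts a root only
below residual 1e−10. Exact `β = 4α` is classified isogamy (the
branches coincide; a measure-zero tie).

Stability is classified two ways, and reported separately, because the
underlying criteria genuinely differ:

* **convergence stability** — eigenvalues of the closed-form Jacobian
  of the gradient system; both real parts below −1e−9 counts as stable.
  On the isogamous diagonal the eigenvalues are `(β/4 − α)/m³` and
  `−(α + β/4)/m³` with `m = α + β/4`: the leading one changes sign
  exactly at `β = 4α`, which is how the threshold detector works.
* **global uninvadability** — a rare-mutant scan: invasion gain
  `ln w(mutant, resident partner) − ln w(resident, resident partner)`
  evaluated on a 400-point log grid of mutant sizes over `[δ, M]` in
  both roles; gains above 1e−9 count as invasion.

Local tests alone would mislead in the power-law variant, where the
interior singular point is a repeller and outcomes sit on boundaries;
boundary points whose outward coordinates have outward-pointing
gradients are admitted as (boundary-)equilibria.

Thresholds are located by bisection on these boolean criteria to
bracket width 1e−6 (`find_threshold`), as an independent check of the
analytically known values (`classify_regime` reports those directly).

### The power-law exponent and the vanishing-cutoff limit

In the threshold-survival variant with `f = c(x+y)^h`, the condition
for anisogamy is structural: `h·k > 1`. Any concrete invasibility scan,
however, must use a finite viability cutoff δ, and the detected
threshold then carries a systematic bias: the hardest invader against
the `(δ, δ)` resident is the whole-budget mutant `x = M`, whose gain
crosses zero at

    h*(δ) = ln(M/δ) / (k · ln((M+δ)/(2δ)))  =  (1/k)(1 + ln2/L + O(1/L²)),   L = ln(M/δ),

which exceeds `1/k` by ≈11% even at δ/M = 1e−3 and converges only
logarithmically as δ → 0. `cutoff_free_critical_exponent` therefore
runs the per-δ bisection over a decreasing sequence
δ ∈ {1e−3, …, 1e−8} and extrapolates a quadratic polynomial in
`u = 1/L` to `u = 0` — `h*(u)` is analytic in `u`, so the polynomial
extrapolation converges fast (residual ≈ 1e−4 with these six points).
The extrapolated value is the cutoff-free exponent the structural
condition refers to; the per-δ values are reported alongside it.

## Gradient dynamics

`integrate` runs explicit Euler on
`dx/dt = ∂ln w_x/∂x, dy/dt = ∂ln w_y/∂y` with coordinates clamped to
the strategy box (`[δ, M]` under the threshold variant, `(0, M]`
otherwise, with a tiny positive floor for numerical safety). The
canonical-equation prefactor (mutational variance × population size) is
set to 1, so time units are arbitrary: the package needs directions and
limit points, not waiting times. Euler with a fixed step (default
1e−2 × the smallest survival scale) was chosen over adaptive schemes
because the flow is smooth, two-dimensional and cheap, and correctness
of a limit point is certified by its gradient residual, not by the
integrator; the test suite additionally checks that step-halving moves
limit points by < 1e−6. Convergence uses the *projected* gradient
(outward components at clamped coordinates zeroed), so boundary-pinned
outcomes such as oogamy-like extreme dimorphism (macro at *M*, micro at
δ) count as converged. The exactly symmetric diagonal is invariant
under the dynamics; reaching the anisogamous branch requires an
asymmetric start, which is why the CLI's default start carries a 1e−3
perturbation.

## Gamete limitation

Fertilization models are built from a count function `F(n_x, n_y)`
(contract: `0 ≤ F ≤ min(n_x, n_y)`, symmetric; checked at every call)
with per-gamete probabilities derived as `p = F/n`. This enforces the
Fisher condition `p_x n_x = p_y n_y = F` by construction instead of by
assumption. Two built-ins ship — complete fertilization `F = min` and a
saturating mass-action form `F = n_x n_y/(n_x + n_y + s)` — as
illustrative contracts only; no claim is made that they match any
particular fertilization-kinetics model, and users can register their
own under the same contract.

Under panmixia a rare mutant's gametes are diluted over the whole
population, so `p` is not a function of the mutant's own trait: its log
is an additive constant, the panmictic gradient is exactly the bare
model's, and all equilibria are unchanged — however small `F` is scaled
(arbitrarily severe gamete limitation coexists with full-strength
gamete competition). The local-group mode implements only the minimal
illustrative case (one focal pair per group, the focal parent's own
output sets the local count, so mutant log fitness is
`ln F(n(x'), n_partner) + ln g + ln f`), differentiated by central
finite differences because `F` is pluggable; full group-size-dependent
analysis is out of scope.

## Numerical choices

| quantity | value | where |
|---|---|---|
| equilibrium residual | 1e−10 | `solve_equilibrium` |
| eigenvalue sign deadband | 1e−9 | `stability_at` |
| invasion-gain tolerance | 1e−9 | mutant scans |
| mutant scan grid | 400 points, log-spaced on `[δ, M]` | scans |
| bisection bracket width | 1e−6 | `find_threshold` |
| Euler step | 1e−2 × min(α, β) (exponential) / 1e−2 M (power) | `integrate` |
| finite-difference step (tests, local-group gradients) | 1e−6 × scale, central | — |

All defaults are overridable per call. Problem sizes used by the test
suite and the acceptance script — 3×20×3 parameter grids for the
closed-form/oracle agreement, a handful of trajectories, six δ values
for the cutoff extrapolation — were chosen so the full check runs in
seconds while leaving the verified tolerances comfortably slack.

## What the checks do and do not show

There is no external data anywhere: every fixture is generated by the
model's own closed forms or by the independent numerical oracle, so the
tests certify *internal* correctness and robustness of the model family
(exact solutions, their stability, their invariances, the behaviour of
the approximation), not empirical adequacy. In particular the model's
robustness cuts both ways: because qualitatively similar outcomes arise
across a range of component functions, quantitative outputs (the size
ratio, the switch point) shift with those functions, and the
approximate-solution "ratio > 3 at onset" figure is reproduced here
explicitly as an artefact demonstration, not endorsed as a prediction.

Known limitations: two mating types only; no genetics; the local-group
limitation mode is the minimal illustrative case; gamete target-size
(collision cross-section) effects on fertilization are not modelled;
the power-law variant's outcomes depend on the cutoff δ by construction
(hence the extrapolation machinery above).
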