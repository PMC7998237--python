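# anisogame

Game-theoretic models of gamete-size evolution: exact and approximate
equilibria of the gamete-competition game behind the evolution of
anisogamy (gamete size dimorphism — the origin of eggs, sperm, and
thereby the two sexes), with stability and invasibility analysis,
generalized gamete size–number trade-offs, gradient ("adaptive")
dynamics, and a Fisher-consistent gamete-limitation extension.

Intended for theoreticians in evolutionary biology who want a tested,
scriptable reference implementation of this model family — to reproduce
the classical results, probe their robustness, or build variants on top
of the same machinery.

## The model

Two pre-existing mating types make gametes of sizes *x* and *y* from a
fixed budget *M*. Fitness of the *x*-type is

    w_x(x, y) = n(x) · g(x) · f(x, y)

with the size–number trade-off `n(x) = (M/x)^{1/k}` (k ≥ 1; k > 1 means
resource is lost when the budget is divided into many small gametes),
gamete survival `g(x) = exp(−α/x)` (or a viability threshold at size δ),
and zygote survival `f(x, y) = exp(−β/(x+y))` (or a power law
`c·(x+y)^h`). Selection follows the log-fitness gradients
∂ln w_x/∂x, ∂ln w_y/∂y, whose zeros are the evolutionary equilibria.

Headline results implemented and verified here:

* **Exact equilibria.** Isogamy at `x = y = k(α + β/4)`; for `β > 4α` an
  anisogamous equilibrium with sum constraint `x + y = kβ` and sizes
  `(kβ/2)(1 ± √(1 − 4α/β))`. The isogamous state loses stability exactly
  at `β = 4α`, independent of *k* and *M*.
* **Onset artefact.** The binomial-approximation solution
  `(x, y) ≈ k(β−α), kα` predicts a macro:micro ratio jumping from 1 to 3
  at onset; the exact ratio `(1+√(1−4α/β))/(1−√(1−4α/β))` rises
  continuously from 1. The jump is an artefact of the approximation,
  not a model prediction.
* **Power-law condition.** With a viability threshold for gametes and
  `f = c(x+y)^h`, anisogamy becomes possible exactly when `h·k > 1`:
  a convex zygote-survival function is unnecessary if the size–number
  trade-off is inefficient.
* **Gamete limitation.** Adding per-gamete fertilization probabilities
  `p_x n_x = p_y n_y = F` restores the Fisher condition (equal total
  reproductive success through the two types); under panmixia this
  leaves every equilibrium unchanged, however severe the limitation.

## Worked example

Solve the exponential-survival model at α=1, β=8 (anisogamous regime):

```bash
anisogame solve --M 100 --alpha 1 --beta 8
```

prints (abridged):

```json
{
  "regime": "anisogamy",
  "closed_form": {"x": 6.82842712474619, "y": 1.1715728752538097,
                  "ratio": 5.828427124746191},
  "numerical":   {"x": 6.828427124746192, "y": 1.17157287525381,
                  "gradient_residual": 5.551115123125783e-17},
  "agreement": 2.601414362266152e-16,
  "stability": {"convergence_stable": true,
                "globally_uninvadable": true,
                "jacobian_eigenvalues": [-0.014249882958827, -0.548250117041173]}
}
```

Because β = 8 > 4α, isogamy is unstable and the stable state is
anisogamous: the macrogamete is ≈6.83, the microgamete ≈1.17 (their sum
is exactly β), the size ratio is 3 + 2√2 ≈ 5.83, and the point is both
convergence stable (negative Jacobian eigenvalues of the gradient
system) and uninvadable by any mutant on the scan grid. The independent
numerical root-finder agrees with the closed form to machine precision.

Other commands: `anisogame scan` (bisect β or h to the regime
threshold), `anisogame ratio-curve` (exact vs approximate ratio table
and figure), `anisogame trajectory` (gradient dynamics to CSV/figure),
`anisogame limitation-audit` (Fisher-condition audit at a point). All
accept `--config params.json` with flags taking precedence.

The same functionality is available as a library:

```python
from anisogame import ModelParams, stable_equilibrium, find_threshold

params = ModelParams(M=100, alpha=1, beta=8)
eq = stable_equilibrium(params)            # x≈6.8284, y≈1.1716
scan = find_threshold(params, "beta", (1, 10), "isogamy_destabilised")
print(eq.sizes, scan.critical_value)       # beta_crit = 4.000000
```

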