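"""Closed-form equilibria, approximations, size ratios, and regime classification.

For the exponential survival forms the gradient system has an exact
solution.  Writing the isogamous equilibrium as ``x = y = k*(alpha + beta/4)``
and using the anisogamous sum constraint ``x + y = k*beta``, the full set
of stable equilibria is piecewise in ``beta/alpha``:

* ``beta <= 4*alpha`` — isogamy, ``x = y = k*(alpha + beta/4)``;
* ``beta > 4*alpha`` — anisogamy, ``x, y = (k*beta/2)*(1 ± sqrt(1 - 4*alpha/beta))``.

The widely quoted approximation replaces the square root by its first-order
binomial expansion, giving ``(x, y) ≈ k*(beta - alpha), k*alpha``.  The
approximate macro:micro ratio then jumps discontinuously from 1 to 3 at the
onset of anisogamy, whereas the exact ratio rises continuously from 1 — the
jump is an artefact of the approximation, not a model prediction.

The trade-off exponent ``k`` multiplies all equilibrium sizes but cancels
from both the threshold (``beta = 4*alpha``) and the size ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional

from . import core
from .errors import UnsupportedVariantError
from .params import EXPONENTIAL, POWER, GameteSizePair, ModelParams

ISOGAMY = "isogamy"
ANISOGAMY = "anisogamy"

CLOSED_FORM = "closed_form"
APPROXIMATION = "approximation"
NUMERICAL = "numerical"


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium with macro-convention sizes and provenance.

    ``sizes.x`` is always the macrogamete (larger) size; which mating
    type actually ends up macro is a matter of evolutionary history and
    is resolved by the adaptive-dynamics module, not here.
    """

    sizes: GameteSizePair
    regime: str
    source: str
    gradient_residual: float
    stability: Optional[object] = None

    def __post_init__(self) -> None:
        if self.sizes.x < self.sizes.y:
            object.__setattr__(self, "sizes", self.sizes.swapped())

    def with_stability(self, record) -> "EquilibriumResult":
        return _dc_replace(self, stability=record)

    @property
    def ratio(self) -> float:
        return self.sizes.ratio


@dataclass(frozen=True)
class RegimeResult:
    """Regime label plus the analytic critical parameter value."""

    regime: str
    threshold_parameter: str  # "beta" or "h"
    threshold_value: float


def _require_exponential(params: ModelParams) -> None:
    if (
        params.gamete_survival_form != EXPONENTIAL
        or params.zygote_survival_form != EXPONENTIAL
    ):
        raise UnsupportedVariantError(
            "closed-form equilibria are available only for the exponential "
            f"survival forms, got gamete={params.gamete_survival_form!r}, "
            f"zygote={params.zygote_survival_form!r}"
        )


def _residual(sizes: GameteSizePair, params: ModelParams) -> float:
    g = core.selection_gradient(sizes, params)
    return max(abs(g[0]), abs(g[1]))


def isogamous_equilibrium(params: ModelParams) -> EquilibriumResult:
    """Isogamous equilibrium ``x = y = k*(alpha + beta/4)`` (no stability claim)."""
    _require_exponential(params)
    m = params.k * (params.alpha + params.beta / 4.0)
    sizes = GameteSizePair(m, m)
    return EquilibriumResult(
        sizes=sizes,
        regime=ISOGAMY,
        source=CLOSED_FORM,
        gradient_residual=_residual(sizes, params),
    )


def anisogamous_equilibrium(params: ModelParams) -> Optional[EquilibriumResult]:
    """Anisogamous root pair, or ``None`` when no real solution exists.

    Real solutions require ``beta >= 4*alpha``; the sum constraint
    ``x + y = k*beta`` holds exactly.  At equality the root is the
    degenerate ``x = y = 2*k*alpha``, coinciding with isogamy.
    """
    _require_exponential(params)
    a, b, k = params.alpha, params.beta, params.k
    if b < 4.0 * a or b == 0.0:
        return None
    s = math.sqrt(1.0 - 4.0 * a / b)
    x = 0.5 * k * b * (1.0 + s)
    y = 0.5 * k * b * (1.0 - s)
    sizes = GameteSizePair(x, y)
    return EquilibriumResult(
        sizes=sizes,
        regime=ANISOGAMY if x > y else ISOGAMY,
        source=CLOSED_FORM,
        gradient_residual=_residual(sizes, params),
    )


def stable_equilibrium(params: ModelParams) -> EquilibriumResult:
    """The stable branch: isogamy for ``beta <= 4*alpha``, anisogamy above.

    Continuous in (alpha, beta): both branches equal ``2*k*alpha`` at the
    threshold.
    """
    _require_exponential(params)
    if params.beta <= 4.0 * params.alpha:
        return isogamous_equilibrium(params)
    res = anisogamous_equilibrium(params)
    assert res is not None
    return res


def approximate_equilibrium(params: ModelParams) -> Optional[EquilibriumResult]:
    """Binomial-approximation anisogamous sizes ``k*(beta - alpha), k*alpha``.

    Accurate only far above the threshold; returns ``None`` for
    ``beta <= 4*alpha``.  The reported gradient residual is the genuine
    (nonzero) residual of the approximation.
    """
    _require_exponential(params)
    a, b, k = params.alpha, params.beta, params.k
    if b <= 4.0 * a:
        return None
    sizes = GameteSizePair(k * (b - a), k * a)
    return EquilibriumResult(
        sizes=sizes,
        regime=ANISOGAMY,
        source=APPROXIMATION,
        gradient_residual=_residual(sizes, params),
    )


def exact_ratio_of(beta_over_alpha: float) -> float:
    """Exact macro:micro ratio as a function of ``beta/alpha`` (1 at/below 4)."""
    if beta_over_alpha <= 4.0:
        return 1.0
    s = math.sqrt(1.0 - 4.0 / beta_over_alpha)
    return (1.0 + s) / (1.0 - s)


def approximate_ratio_of(beta_over_alpha: float) -> float:
    """Approximate ratio ``beta/alpha - 1`` on the anisogamous branch.

    Evaluated on the anisogamous branch from the threshold upward, so it
    exhibits the onset jump 1 -> 3 at ``beta/alpha = 4``.
    """
    if beta_over_alpha < 4.0:
        return 1.0
    return beta_over_alpha - 1.0


def size_ratio(params: ModelParams, method: str = "exact") -> float:
    """Macro:micro gamete-size ratio, independent of ``k`` and ``M``.

    ``method="exact"`` uses the closed-form root ratio; ``"approximate"``
    uses ``beta/alpha - 1``.  Both return 1 at and below the threshold
    (equality is classified as isogamy).
    """
    _require_exponential(params)
    if params.alpha == 0.0:
        return math.inf if params.beta > 0 else 1.0
    b_over_a = params.beta / params.alpha
    if method == "exact":
        return exact_ratio_of(b_over_a)
    if method == "approximate":
        return 1.0 if b_over_a <= 4.0 else b_over_a - 1.0
    raise ValueError(f"method must be 'exact' or 'approximate', got {method!r}")


def onset_ratios(threshold_beta_over_alpha: float = 4.0) -> tuple[float, float]:
    """(exact, approximate) ratio limits as anisogamy sets on.

    Approaching the threshold from the anisogamous side, the exact ratio
    tends to 1 (continuous onset) while the approximate anisogamous
    branch evaluates to ``beta/alpha - 1`` = 3 — the discontinuity
    artefact of the binomial approximation.
    """
    exact = 1.0  # sqrt term vanishes at the threshold: continuous onset
    approximate = threshold_beta_over_alpha - 1.0
    return (exact, approximate)


def classify_regime(params: ModelParams) -> RegimeResult:
    """Regime label plus analytic threshold for the selected variant.

    Exponential zygote survival: anisogamy iff ``beta > 4*alpha``
    (threshold independent of ``k`` and ``M``).  Power-law zygote
    survival: anisogamy iff ``h*k > 1``, i.e. critical exponent
    ``h_crit = 1/k``.  Equality is classified as isogamy.
    """
    if params.zygote_survival_form == EXPONENTIAL:
        beta_crit = 4.0 * params.alpha
        regime = ANISOGAMY if params.beta > beta_crit else ISOGAMY
        return RegimeResult(regime=regime, threshold_parameter="beta", threshold_value=beta_crit)
    if params.zygote_survival_form == POWER:
        h_crit = 1.0 / params.k
        regime = ANISOGAMY if params.h * params.k > 1.0 else ISOGAMY
        return RegimeResult(regime=regime, threshold_parameter="h", threshold_value=h_crit)
    raise UnsupportedVariantError(
        f"unsupported zygote survival form {params.zygote_survival_form!r}"
    )
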