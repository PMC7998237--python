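"""Component functions, fitness, and closed-form selection gradients.

Fitness of a focal parent of mating type *x* with gamete size ``x`` in a
resident population where the opposite type makes gametes of size ``y`` is

    w_x(x, y) = n(x) * g(x) * f(x, y)

(number of gametes, times the fraction surviving to fertilization, times
zygote survival).  Selection acts on the log-fitness gradient; its zeros
are the evolutionary equilibria.  The same function serves both mating
types with the roles of the arguments swapped.

All derivatives here are closed-form per functional-form combination.
Note that the resource budget ``M`` enters log fitness only through the
additive term ``ln(M)/k`` and therefore cancels from every gradient and
Hessian: derivative evaluations accept any positive size, while the
budget cap ``x <= M`` is enforced where gamete numbers are computed and
by the strategy bounds of solvers and dynamics.
"""

from __future__ import annotations

import math

from .errors import DomainError, UnsupportedVariantError
from .params import (
    EXPONENTIAL,
    POWER,
    THRESHOLD,
    GameteSizePair,
    ModelParams,
    TradeoffReparam,
)

#: log-fitness sentinel for an inviable gamete (size below the viability
#: threshold).  Distinct from a DomainError: optimizers treat it as an
#: absorbing worst case rather than a programming error.
INVIABLE = -math.inf


def gamete_number(x: float, params: ModelParams) -> float:
    """Number of gametes ``n = (M/x)**(1/k)`` a parent makes at size ``x``.

    Strictly decreasing in ``x``; the whole budget in one gamete gives
    ``n(M) = 1``.  Requires ``0 < x <= M``.
    """
    if not (x > 0):
        raise DomainError(f"gamete size must be positive, got x={x}")
    if x > params.M:
        raise DomainError(
            f"gamete size x={x} exceeds the resource budget M={params.M}"
        )
    return (params.M / x) ** (1.0 / params.k)


def reparametrise_tradeoff(
    k: float, d: int, M: float
) -> TradeoffReparam:
    """Cell-division reparametrisation of the trade-off ``x = M / n**k``.

    ``d`` binary division rounds give ``n = 2**d`` gametes of size
    ``x = M * q**d / 2**d`` with retained-resource fraction
    ``q = 2**(1-k)``; the round trip ``k -> q -> k`` is exact.
    """
    if k < 1:
        raise DomainError(f"trade-off exponent k must be >= 1, got {k}")
    if M <= 0:
        raise DomainError(f"resource budget M must be positive, got {M}")
    q = 2.0 ** (1.0 - k)
    n = 2.0**d
    x = M * q**d / n
    return TradeoffReparam(q=q, d=d, n=n, gamete_size=x)


def gamete_survival(size: float, params: ModelParams) -> float:
    """Probability that a gamete of the given size survives to fertilization."""
    if not (size > 0):
        raise DomainError(f"gamete size must be positive, got {size}")
    if params.gamete_survival_form == EXPONENTIAL:
        if params.alpha == 0:
            return 1.0
        return math.exp(-params.alpha / size)
    # threshold: all gametes at or above the minimum viable size survive
    return 1.0 if size >= params.delta else 0.0


def zygote_survival(x: float, y: float, params: ModelParams) -> float:
    """Zygote survival as a function of total provisioning ``x + y``.

    The exponential form is a probability in (0, 1]; the power form
    ``c*(x+y)**h`` is an uncapped fitness factor (eventual saturation is
    not needed for the questions this model family answers).
    """
    if not (x > 0 and y > 0):
        raise DomainError(f"gamete sizes must be positive, got x={x}, y={y}")
    s = x + y
    if params.zygote_survival_form == EXPONENTIAL:
        if params.beta == 0:
            return 1.0
        return math.exp(-params.beta / s)
    return params.c * s**params.h


def log_fitness(focal_size: float, partner_size: float, params: ModelParams) -> float:
    """``ln[n(focal) * g(focal) * f(focal, partner)]`` for the selected forms.

    Under the threshold gamete-survival form a focal size below ``delta``
    returns the ``INVIABLE`` sentinel (``-inf``) rather than raising.
    """
    if not (focal_size > 0 and partner_size > 0):
        raise DomainError(
            f"gamete sizes must be positive, got focal={focal_size}, partner={partner_size}"
        )
    k = params.k
    ln_n = (math.log(params.M) - math.log(focal_size)) / k

    if params.gamete_survival_form == EXPONENTIAL:
        ln_g = -params.alpha / focal_size
    else:
        if focal_size < params.delta:
            return INVIABLE
        ln_g = 0.0

    s = focal_size + partner_size
    if params.zygote_survival_form == EXPONENTIAL:
        ln_f = -params.beta / s
    else:
        ln_f = math.log(params.c) + params.h * math.log(s)

    return ln_n + ln_g + ln_f


def fitness(focal_size: float, partner_size: float, params: ModelParams) -> float:
    """Absolute fitness ``n * g * f``; zero for an inviable gamete."""
    lw = log_fitness(focal_size, partner_size, params)
    return math.exp(lw) if lw != INVIABLE else 0.0


def _dlng(size: float, params: ModelParams) -> float:
    if params.gamete_survival_form == EXPONENTIAL:
        return params.alpha / size**2
    if size < params.delta:
        raise DomainError(
            f"selection gradient undefined for inviable gamete size {size} < delta={params.delta}"
        )
    return 0.0


def _dlnf(s: float, params: ModelParams) -> float:
    # derivative of ln f with respect to the focal size; depends on x+y only
    if params.zygote_survival_form == EXPONENTIAL:
        return params.beta / s**2
    return params.h / s


def selection_gradient(
    point: GameteSizePair, params: ModelParams
) -> tuple[float, float]:
    """Closed-form ``(d ln w_x / dx, d ln w_y / dy)`` at a resident point.

    For the exponential forms this is
    ``alpha/x**2 + beta/(x+y)**2 - 1/(k*x)`` (and the same with roles
    swapped); both components vanish at the analytic equilibria.
    """
    _check_forms(params)
    x, y = point.x, point.y
    s = x + y
    gx = -1.0 / (params.k * x) + _dlng(x, params) + _dlnf(s, params)
    gy = -1.0 / (params.k * y) + _dlng(y, params) + _dlnf(s, params)
    return (gx, gy)


def gradient_jacobian(
    point: GameteSizePair, params: ModelParams
) -> list[list[float]]:
    """Closed-form 2x2 Jacobian of the selection-gradient system in (x, y).

    Row i is the derivative of gradient component i with respect to
    (x, y).  Used for convergence-stability classification.
    """
    _check_forms(params)
    x, y = point.x, point.y
    s = x + y

    if params.zygote_survival_form == EXPONENTIAL:
        d2f = -2.0 * params.beta / s**3
    else:
        d2f = -params.h / s**2

    def d2g(size: float) -> float:
        if params.gamete_survival_form == EXPONENTIAL:
            return -2.0 * params.alpha / size**3
        return 0.0

    dgx_dx = 1.0 / (params.k * x**2) + d2g(x) + d2f
    dgy_dy = 1.0 / (params.k * y**2) + d2g(y) + d2f
    return [[dgx_dx, d2f], [d2f, dgy_dy]]


def _check_forms(params: ModelParams) -> None:
    if params.gamete_survival_form not in (EXPONENTIAL, THRESHOLD):
        raise UnsupportedVariantError(
            f"unsupported gamete survival form {params.gamete_survival_form!r}"
        )
    if params.zygote_survival_form not in (EXPONENTIAL, POWER):
        raise UnsupportedVariantError(
            f"unsupported zygote survival form {params.zygote_survival_form!r}"
        )
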