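"""Gamete limitation: Fisher-consistent fitness with fertilization probabilities.

The bare fitness ``w = n * g * f`` has a seemingly paradoxical property:
at an anisogamous point the two mating types have unequal fitness, yet
every zygote has exactly one parent of each type, so total reproductive
success through the two types must be equal (the Fisher condition).

Consistency is restored by a per-gamete fertilization probability ``p``:

    w_x = p_x * n_x * g_x * f(x, y),    w_y = p_y * n_y * g_y * f(x, y)

with ``p_x * n_x = p_y * n_y = F``, the number of fertilizations.  Here
fertilization models are built from a fertilization-count function
``F(n_x, n_y)`` with ``p = F/n`` derived from it, which enforces the
Fisher condition by construction rather than by assumption.

Whether the ``p`` term changes evolutionary outcomes depends on
population structure.  In a large panmictic population a rare mutant's
gametes are diluted over everyone's: ``p`` is not a function of the
mutant's own output, its log contributes an additive constant, and the
selection gradients — hence all equilibria — are exactly those of the
bare model, however severe the gamete limitation.  In small local
spawning groups the focal parent's own output shifts local gamete
density, ``p`` varies with the mutant trait, and gradients (and
potentially equilibria) change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from . import core
from .errors import DomainError, ModelContractError
from .params import GameteSizePair, ModelParams

PANMICTIC = "panmictic"
LOCAL_GROUP = "local_group"

_CONTRACT_RTOL = 1e-12


@dataclass(frozen=True)
class FertilizationModel:
    """A named fertilization-count function ``F(n_x, n_y)``.

    Contract (checked at every evaluation): ``0 <= F <= min(n_x, n_y)``
    and ``F`` symmetric under swapping its arguments.
    """

    name: str
    count_function: Callable[[float, float], float]

    def count(self, n_x: float, n_y: float) -> float:
        if not (n_x > 0 and n_y > 0):
            raise DomainError(f"gamete numbers must be positive, got {n_x}, {n_y}")
        F = float(self.count_function(n_x, n_y))
        bound = min(n_x, n_y)
        if not (-_CONTRACT_RTOL * bound <= F <= bound * (1 + _CONTRACT_RTOL)):
            raise ModelContractError(
                f"fertilization model {self.name!r} returned F={F} outside "
                f"[0, min(n_x, n_y)]=[0, {bound}]"
            )
        return min(max(F, 0.0), bound)


def complete_fertilization() -> FertilizationModel:
    """Every gamete of the rarer type is fertilized: ``F = min(n_x, n_y)``."""
    return FertilizationModel("complete", lambda nx, ny: min(nx, ny))


def saturating_fertilization(s: float = 0.0) -> FertilizationModel:
    """Mass-action-like saturating count ``F = n_x*n_y / (n_x + n_y + s)``.

    ``s >= 0`` is an inefficiency parameter; larger ``s`` means fewer
    fertilizations at the same gamete numbers.
    """
    if s < 0:
        raise DomainError(f"saturation parameter s must be >= 0, got {s}")
    return FertilizationModel("saturating", lambda nx, ny: nx * ny / (nx + ny + s))


def scaled(model: FertilizationModel, efficiency: float) -> FertilizationModel:
    """Scale a model's count by a factor in (0, 1] (severe gamete limitation)."""
    if not (0 < efficiency <= 1):
        raise DomainError(f"efficiency must lie in (0, 1], got {efficiency}")
    return FertilizationModel(
        f"{model.name}*{efficiency:g}",
        lambda nx, ny: efficiency * model.count_function(nx, ny),
    )


_REGISTRY: dict[str, Callable[..., FertilizationModel]] = {
    "complete": lambda **kw: complete_fertilization(),
    "saturating": lambda **kw: saturating_fertilization(kw.get("s", 0.0)),
}


def register_model(name: str, factory: Callable[..., FertilizationModel]) -> None:
    """Register a user fertilization-model factory under a config name."""
    _REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> FertilizationModel:
    if name not in _REGISTRY:
        raise DomainError(
            f"unknown fertilization model {name!r}; available: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


@dataclass(frozen=True)
class LimitedFitnessResult:
    w_x: float
    w_y: float
    log_w_x: float
    log_w_y: float
    p_x: float
    p_y: float
    fertilizations: float
    fisher_gap: float


@dataclass(frozen=True)
class FisherAudit:
    """Fisher-condition gaps of the limited and of the bare fitness."""

    limited_gap: float
    bare_gap: float


def fertilization_probabilities(
    n_x: float, n_y: float, model: FertilizationModel
) -> tuple[float, float, float]:
    """Per-gamete fertilization probabilities ``(p_x, p_y, F)``.

    ``p_x * n_x = p_y * n_y = F`` holds exactly by construction.
    """
    F = model.count(n_x, n_y)
    return (F / n_x, F / n_y, F)


def limited_log_fitness(
    point: GameteSizePair,
    params: ModelParams,
    model: FertilizationModel,
    structure: str = PANMICTIC,
) -> LimitedFitnessResult:
    """Fisher-consistent fitness ``p * n * g * f`` of both types at a point.

    The point value does not depend on ``structure`` (structure matters
    for gradients, see :func:`limited_selection_gradient`).
    """
    _check_structure(structure)
    x, y = point.x, point.y
    n_x = core.gamete_number(x, params)
    n_y = core.gamete_number(y, params)
    p_x, p_y, F = fertilization_probabilities(n_x, n_y, model)
    g_x = core.gamete_survival(x, params)
    g_y = core.gamete_survival(y, params)
    f = core.zygote_survival(x, y, params)
    w_x = p_x * n_x * g_x * f
    w_y = p_y * n_y * g_y * f
    log_w_x = math.log(w_x) if w_x > 0 else -math.inf
    log_w_y = math.log(w_y) if w_y > 0 else -math.inf
    return LimitedFitnessResult(
        w_x=w_x,
        w_y=w_y,
        log_w_x=log_w_x,
        log_w_y=log_w_y,
        p_x=p_x,
        p_y=p_y,
        fertilizations=F,
        fisher_gap=abs(p_x * n_x - p_y * n_y),
    )


def limited_selection_gradient(
    point: GameteSizePair,
    params: ModelParams,
    model: FertilizationModel,
    structure: str = PANMICTIC,
    fd_step_scale: float = 1e-6,
) -> tuple[float, float]:
    """Selection gradient of the gamete-limited fitness at a resident point.

    Panmictic structure: a rare mutant does not move the population-level
    fertilization probabilities, ``ln p`` is an additive constant in the
    mutant trait, and the gradient equals the bare model's closed form
    exactly.

    Local-group structure (minimal illustrative case: one focal pair per
    group): the focal parent's own gamete number sets the local count, so
    mutant log fitness is ``ln F(n(x'), n_partner) + ln g(x') + ln f(x', y)``
    (note ``p*n = F``); differentiated by central finite differences
    because ``F`` is pluggable.
    """
    _check_structure(structure)
    if structure == PANMICTIC:
        return core.selection_gradient(point, params)

    x, y = point.x, point.y
    n_y = core.gamete_number(y, params)
    n_x = core.gamete_number(x, params)

    def ln_w(role_size: float, partner_size: float, partner_n: float) -> float:
        n_m = core.gamete_number(role_size, params)
        F = model.count(n_m, partner_n)
        g = core.gamete_survival(role_size, params)
        f = core.zygote_survival(role_size, partner_size, params)
        if F <= 0 or g <= 0:
            return -math.inf
        return math.log(F) + math.log(g) + math.log(f)

    def central(fn, at: float) -> float:
        hstep = fd_step_scale * at
        return (fn(at + hstep) - fn(at - hstep)) / (2.0 * hstep)

    gx = central(lambda v: ln_w(v, y, n_y), x)
    gy = central(lambda v: ln_w(v, x, n_x), y)
    return (gx, gy)


def fisher_condition_audit(
    point: GameteSizePair, params: ModelParams, model: FertilizationModel
) -> FisherAudit:
    """Audit the Fisher condition at a strategy point.

    ``limited_gap = |p_x n_x - p_y n_y|`` is zero to machine precision
    for every model built from a count function.  ``bare_gap`` is the
    per-capita fitness gap of the bare ``n*g*f`` model — generally
    nonzero under anisogamy (``n_x != n_y``), zero under isogamy.
    """
    res = limited_log_fitness(point, params, model)
    w_x_bare = core.fitness(point.x, point.y, params)
    w_y_bare = core.fitness(point.y, point.x, params)
    return FisherAudit(limited_gap=res.fisher_gap, bare_gap=abs(w_x_bare - w_y_bare))


def _check_structure(structure: str) -> None:
    if structure not in (PANMICTIC, LOCAL_GROUP):
        raise DomainError(
            f"structure must be {PANMICTIC!r} or {LOCAL_GROUP!r}, got {structure!r}"
        )
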