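"""Parameters and strategy types for the gamete-competition game.

The model family describes a broadcast-spawning population with two
pre-existing mating types whose gamete sizes ``x`` and ``y`` evolve under
two opposing selection pressures: numerical productivity (many small
gametes win more fertilizations) and zygote provisioning (large gametes
make better-provisioned, better-surviving zygotes).

Three component functions define a model variant:

* size–number trade-off  ``n(x) = (M/x)**(1/k)`` — a parent with budget
  ``M`` makes ``n`` gametes of size ``x``; ``k > 1`` means resource is
  lost when dividing the budget into many small gametes;
* gamete survival ``g(x)`` — either ``exp(-alpha/x)`` (smooth
  size-dependent mortality) or a viability threshold (all gametes of size
  at least ``delta`` survive);
* zygote survival ``f(x, y)`` — either ``exp(-beta/(x+y))`` (saturating
  in total provisioning) or a power law ``c*(x+y)**h``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import DomainError

EXPONENTIAL = "exponential"
THRESHOLD = "threshold"
POWER = "power"

_GAMETE_FORMS = (EXPONENTIAL, THRESHOLD)
_ZYGOTE_FORMS = (EXPONENTIAL, POWER)


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the model family plus functional-form selectors.

    Parameters
    ----------
    M : float
        Total gametic resource budget per parent (arbitrary mass units), > 0.
    alpha : float
        Gamete-survival scale (size units), >= 0. Larger ``alpha`` means
        stronger size-dependent gamete mortality.
    beta : float
        Zygote-survival scale (size units), >= 0. Larger ``beta`` means
        stronger dependence of zygote survival on total provisioning.
    k : float
        Trade-off inefficiency exponent, >= 1 (dimensionless); ``k = 1``
        is the exact, lossless size–number trade-off.
    c : float
        Proportionality constant of the power-law zygote survival, > 0.
    h : float
        Power-law zygote-survival exponent, > 0 (dimensionless).
    delta : float
        Minimum viable gamete size (size units), 0 < delta < M; used by
        the threshold gamete-survival variant and as the lower strategy
        bound in scans and dynamics.
    gamete_survival_form : {"exponential", "threshold"}
    zygote_survival_form : {"exponential", "power"}
    """

    M: float = 1.0
    alpha: float = 1.0
    beta: float = 2.0
    k: float = 1.0
    c: float = 1.0
    h: float = 1.0
    delta: float = 1e-3
    gamete_survival_form: str = EXPONENTIAL
    zygote_survival_form: str = EXPONENTIAL

    def __post_init__(self) -> None:
        if not (self.M > 0):
            raise DomainError(f"resource budget M must be positive, got {self.M}")
        if self.alpha < 0 or self.beta < 0:
            raise DomainError(
                f"survival scales must be nonnegative, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.k < 1:
            raise DomainError(f"trade-off exponent k must be >= 1, got {self.k}")
        if not (self.c > 0):
            raise DomainError(f"power-law constant c must be positive, got {self.c}")
        if not (self.h > 0):
            raise DomainError(f"power-law exponent h must be positive, got {self.h}")
        if not (0 < self.delta < self.M):
            raise DomainError(
                f"minimum gamete size delta must satisfy 0 < delta < M, got delta={self.delta}, M={self.M}"
            )
        if self.gamete_survival_form not in _GAMETE_FORMS:
            raise DomainError(
                f"gamete_survival_form must be one of {_GAMETE_FORMS}, got {self.gamete_survival_form!r}"
            )
        if self.zygote_survival_form not in _ZYGOTE_FORMS:
            raise DomainError(
                f"zygote_survival_form must be one of {_ZYGOTE_FORMS}, got {self.zygote_survival_form!r}"
            )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "ModelParams":
        d = self.to_dict()
        d.update(changes)
        return ModelParams(**d)


@dataclass(frozen=True)
class GameteSizePair:
    """A strategy point: gamete sizes of the two mating types."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0):
            raise DomainError(f"gamete sizes must be positive, got x={self.x}, y={self.y}")

    def swapped(self) -> "GameteSizePair":
        return GameteSizePair(self.y, self.x)

    @property
    def macro(self) -> float:
        return max(self.x, self.y)

    @property
    def micro(self) -> float:
        return min(self.x, self.y)

    @property
    def ratio(self) -> float:
        """Macrogamete:microgamete size ratio, >= 1."""
        return self.macro / self.micro

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class TradeoffReparam:
    """Cell-division view of the size–number trade-off.

    ``d`` rounds of binary division produce ``n = 2**d`` gametes; a
    fraction ``1 - q`` of the remaining resource is lost at each round,
    with ``q = 2**(1-k)`` so that the resulting gamete size matches
    ``x = M / n**k`` exactly.
    """

    q: float
    d: int
    n: float
    gamete_size: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise DomainError(f"retained fraction q must lie in (0, 1], got {self.q}")
        if self.d < 0 or self.d != int(self.d):
            raise DomainError(f"division rounds d must be a nonnegative integer, got {self.d}")

    @property
    def k(self) -> float:
        """Recover the trade-off exponent: k = 1 - log2(q)."""
        return 1.0 - math.log2(self.q)
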