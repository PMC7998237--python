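"""Gradient dynamics of the two gamete sizes (adaptive dynamics).

Trait dynamics follow the log-fitness selection gradients,

    dx/dt = d ln w_x / dx,   dy/dt = d ln w_y / dy,

integrated by explicit Euler with a fixed step and coordinates clamped
to the admissible strategy box (``[delta, M]`` for the threshold
gamete-survival variant, ``(0, M]`` otherwise).  The canonical-equation
prefactor (mutational variance, population size) is set to 1 — the model
needs directions and equilibria only — so time units are arbitrary.

A clamped coordinate whose gradient points outward contributes zero to
the convergence check (projected gradient): boundary-pinned states such
as extreme dimorphism (macro at the budget cap, micro at the viability
threshold) count as converged.  Correctness of a limit point is
certified by its gradient residual, not by the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import core
from .errors import DomainError, IntegrationError
from .params import THRESHOLD, GameteSizePair, ModelParams

_FLOOR_FRACTION = 1e-9  # positive floor (fraction of M) for the unclamped variant


@dataclass(frozen=True)
class Trajectory:
    times: tuple[float, ...]
    points: tuple[GameteSizePair, ...]
    converged: bool
    final_residual: float

    @property
    def final(self) -> GameteSizePair:
        return self.points[-1]


def default_step(params: ModelParams) -> float:
    """Conservative fixed Euler step: 1e-2 times the smallest size scale."""
    scales = [s for s in (params.alpha, params.beta) if s > 0]
    if params.zygote_survival_form != "exponential" or not scales:
        return 1e-2 * params.M
    return 1e-2 * min(scales)


def _bounds(params: ModelParams) -> tuple[float, float]:
    lower = params.delta if params.gamete_survival_form == THRESHOLD else _FLOOR_FRACTION * params.M
    return lower, params.M


def _projected_norm(x: float, y: float, gx: float, gy: float, lo: float, hi: float) -> float:
    """Gradient norm with outward-pointing clamped components zeroed."""
    if (x <= lo and gx < 0) or (x >= hi and gx > 0):
        gx = 0.0
    if (y <= lo and gy < 0) or (y >= hi and gy > 0):
        gy = 0.0
    return max(abs(gx), abs(gy))


def integrate(
    initial: GameteSizePair,
    params: ModelParams,
    step: float | None = None,
    max_steps: int = 200_000,
    gradient_tol: float = 1e-9,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the gradient dynamics from an initial strategy point.

    Terminates early once the projected gradient norm falls below
    ``gradient_tol`` (``converged=True``); otherwise runs ``max_steps``
    Euler steps.  ``record_every`` thins the stored trajectory (the final
    state is always recorded).
    """
    if step is None:
        step = default_step(params)
    if not (step > 0):
        raise DomainError(f"integration step must be positive, got {step}")
    if record_every < 1:
        raise DomainError(f"record_every must be >= 1, got {record_every}")

    lo, hi = _bounds(params)
    x = min(max(initial.x, lo), hi)
    y = min(max(initial.y, lo), hi)

    times = [0.0]
    points = [GameteSizePair(x, y)]
    converged = False
    residual = math.inf
    t = 0.0

    for i in range(1, max_steps + 1):
        gx, gy = core.selection_gradient(GameteSizePair(x, y), params)
        residual = _projected_norm(x, y, gx, gy, lo, hi)
        if residual < gradient_tol:
            converged = True
            break
        x = min(max(x + step * gx, lo), hi)
        y = min(max(y + step * gy, lo), hi)
        t = i * step
        if not (math.isfinite(x) and math.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at step {i}",
                last_state=points[-1],
                last_time=times[-1],
            )
        if i % record_every == 0:
            times.append(t)
            points.append(GameteSizePair(x, y))

    if times[-1] != t:
        times.append(t)
        points.append(GameteSizePair(x, y))
    if not converged:
        gx, gy = core.selection_gradient(GameteSizePair(x, y), params)
        residual = _projected_norm(x, y, gx, gy, lo, hi)
        converged = residual < gradient_tol

    return Trajectory(
        times=tuple(times),
        points=tuple(points),
        converged=converged,
        final_residual=residual,
    )
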