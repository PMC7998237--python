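"""Numerical oracle: root finding, stability classification, threshold location.

Everything here is independent of the closed forms in
:mod:`anisogame.analytic`: equilibria are recovered by root finding on
the selection-gradient system, stability is classified from the
gradient-system Jacobian (convergence stability) and from a global
mutant-invasion scan (uninvadability), and regime thresholds are located
by bisection on those criteria.  Agreement between the two routes is a
core correctness check of the package.

Stability is assessed two ways because local and global criteria can
genuinely disagree here: in the power-law zygote-survival variant the
interior singular point is a repeller and the evolutionary outcomes sit
on the strategy-space boundaries, where only the invasion scan is
informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import analytic, core
from .errors import (
    ConvergenceError,
    DomainError,
    NoSignChangeError,
    PreconditionError,
)
from .params import EXPONENTIAL, GameteSizePair, ModelParams

#: default tolerances; overridable per call
RESIDUAL_TOL = 1e-10
EIGENVALUE_DEADBAND = 1e-9
BISECTION_WIDTH = 1e-6
INVASION_TOL = 1e-9
SCAN_GRID_POINTS = 400


@dataclass(frozen=True)
class StabilityRecord:
    """Local (Jacobian) and global (invasion-scan) stability classification."""

    jacobian_eigenvalues: tuple[float, float]
    convergence_stable: bool
    globally_uninvadable: bool
    branching_flag: bool


@dataclass(frozen=True)
class ScanResult:
    """Outcome of a bisection threshold search."""

    parameter_name: str
    values: tuple[float, ...]
    regimes: tuple[str, ...]
    critical_value: float
    bracket: tuple[float, float]
    iterations: int


@dataclass(frozen=True)
class ExtrapolationResult:
    """Cutoff-free critical exponent from a sequence of per-delta bisections.

    The invasibility threshold detected at a finite viability cutoff
    ``delta`` carries a bias of order ``1/ln(M/delta)``; polynomial
    extrapolation in that small quantity recovers the ``delta -> 0``
    limit, which is the exponent the power-law condition refers to.
    """

    critical_value: float
    deltas: tuple[float, ...]
    per_delta_values: tuple[float, ...]
    scans: tuple[ScanResult, ...] = field(repr=False, default=())


# ----------------------------------------------------------------------
# root finding


def _gradient_vec(logxy: np.ndarray, params: ModelParams) -> np.ndarray:
    # solved in log-coordinates so the iterates stay positive
    x, y = math.exp(logxy[0]), math.exp(logxy[1])
    try:
        return np.array(core.selection_gradient(GameteSizePair(x, y), params))
    except DomainError:
        # inviable region (threshold variant): steer the solver away
        return np.array([1e6, 1e6])


def solve_equilibrium(
    params: ModelParams,
    initial: GameteSizePair | None = None,
    residual_tol: float = RESIDUAL_TOL,
) -> analytic.EquilibriumResult:
    """Solve the two-equation gradient system by a hybrid root finder.

    With an explicit ``initial`` the search starts there only; otherwise
    a deterministic multi-start set (diagonal plus the two asymmetric
    corners) is tried and the first root meeting the residual tolerance
    is returned.  Raises :class:`ConvergenceError` (carrying the best
    residual) if no start converges.
    """
    if initial is not None:
        starts = [initial]
    else:
        m = params.k * (params.alpha + params.beta / 4.0)
        if m <= 0:
            m = 0.5 * params.M
        d = params.delta
        starts = [
            GameteSizePair(m, m),
            GameteSizePair(0.9 * params.M, 2.0 * d),
            GameteSizePair(2.0 * d, 0.9 * params.M),
        ]

    best = math.inf
    for start in starts:
        sol = optimize.root(
            _gradient_vec,
            x0=np.log([start.x, start.y]),
            args=(params,),
            method="hybr",
            tol=1e-14,
        )
        sizes = GameteSizePair(*np.exp(sol.x))
        res = max(abs(v) for v in core.selection_gradient(sizes, params))
        best = min(best, res)
        if res < residual_tol:
            regime = (
                analytic.ANISOGAMY
                if not math.isclose(sizes.x, sizes.y, rel_tol=1e-8)
                else analytic.ISOGAMY
            )
            return analytic.EquilibriumResult(
                sizes=sizes,
                regime=regime,
                source=analytic.NUMERICAL,
                gradient_residual=res,
            )
    raise ConvergenceError(
        f"gradient-system root finding did not reach residual {residual_tol:g}; "
        f"best residual {best:g}",
        best_residual=best,
    )


# ----------------------------------------------------------------------
# invasion analysis


def invasion_gain(
    mutant_size: float,
    resident: GameteSizePair,
    role: str,
    params: ModelParams,
) -> float:
    """Log-fitness gain of a rare mutant of the given role against residents.

    ``ln w_role(mutant, resident_partner) - ln w_role(resident_own,
    resident_partner)``; zero when the mutant equals the resident.  An
    inviable mutant (threshold variant) yields ``-inf``.
    """
    if role == "x":
        own, partner = resident.x, resident.y
    elif role == "y":
        own, partner = resident.y, resident.x
    else:
        raise DomainError(f"role must be 'x' or 'y', got {role!r}")
    return core.log_fitness(mutant_size, partner, params) - core.log_fitness(
        own, partner, params
    )


def _max_invasion_gain(
    resident: GameteSizePair,
    params: ModelParams,
    grid_points: int = SCAN_GRID_POINTS,
) -> float:
    """Maximum invasion gain over a log grid of mutant sizes, both roles."""
    grid = np.geomspace(params.delta, params.M, grid_points)
    best = -math.inf
    for role, own, partner in (("x", resident.x, resident.y), ("y", resident.y, resident.x)):
        ln_own = core.log_fitness(own, partner, params)
        # vectorised ln w(mutant, partner); mirrors core.log_fitness
        ln_n = (math.log(params.M) - np.log(grid)) / params.k
        if params.gamete_survival_form == EXPONENTIAL:
            ln_g = -params.alpha / grid
        else:
            ln_g = np.where(grid >= params.delta, 0.0, -math.inf)
        s = grid + partner
        if params.zygote_survival_form == EXPONENTIAL:
            ln_f = -params.beta / s
        else:
            ln_f = math.log(params.c) + params.h * np.log(s)
        best = max(best, float(np.max(ln_n + ln_g + ln_f) - ln_own))
    return best


def stability_at(
    point: GameteSizePair,
    params: ModelParams,
    residual_tol: float = 1e-8,
    eigenvalue_deadband: float = EIGENVALUE_DEADBAND,
    invasion_tol: float = INVASION_TOL,
    grid_points: int = SCAN_GRID_POINTS,
) -> StabilityRecord:
    """Classify an equilibrium: convergence stability and uninvadability.

    The Jacobian of the gradient system is assembled from closed-form
    second derivatives; eigenvalues are reported sorted descending by
    real part.  Global invasibility scans mutant sizes on a log grid over
    ``[delta, M]`` in both roles.
    """
    res = max(abs(v) for v in core.selection_gradient(point, params))
    if res >= residual_tol:
        raise PreconditionError(
            f"stability_at requires an equilibrium (residual < {residual_tol:g}), "
            f"got residual {res:g} at {point}"
        )
    jac = np.array(core.gradient_jacobian(point, params))
    eig = np.linalg.eigvals(jac)
    eig = tuple(sorted((float(v.real) for v in eig), reverse=True))
    convergence_stable = all(v < -eigenvalue_deadband for v in eig)
    uninvadable = _max_invasion_gain(point, params, grid_points) <= invasion_tol
    return StabilityRecord(
        jacobian_eigenvalues=eig,
        convergence_stable=convergence_stable,
        globally_uninvadable=uninvadable,
        branching_flag=convergence_stable and not uninvadable,
    )


# ----------------------------------------------------------------------
# threshold location


def _isogamy_destabilised(params: ModelParams) -> bool:
    """Leading Jacobian eigenvalue at the isogamous equilibrium is positive."""
    iso = analytic.isogamous_equilibrium(params)
    jac = np.array(core.gradient_jacobian(iso.sizes, params))
    leading = float(np.max(np.linalg.eigvals(jac).real))
    return leading > 0.0


def _boundary_invadable(
    params: ModelParams, invasion_tol: float, grid_points: int
) -> bool:
    """Some mutant on the scan grid invades the minimal-size resident."""
    resident = GameteSizePair(params.delta, params.delta)
    return _max_invasion_gain(resident, params, grid_points) > invasion_tol


def find_threshold(
    params: ModelParams,
    parameter_name: str,
    bracket: tuple[float, float],
    criterion: str = "isogamy_destabilised",
    width: float = BISECTION_WIDTH,
    invasion_tol: float = INVASION_TOL,
    grid_points: int = SCAN_GRID_POINTS,
) -> ScanResult:
    """Bisect a model parameter to the regime-change critical value.

    ``criterion="isogamy_destabilised"`` tracks the sign of the leading
    Jacobian eigenvalue at the isogamous equilibrium (exponential
    variant); ``criterion="boundary_invadable"`` tracks whether any
    mutant invades the ``(delta, delta)`` resident (threshold/power
    variant).  Raises :class:`NoSignChangeError` if the criterion is
    constant on the bracket.
    """
    if parameter_name not in ("beta", "h"):
        raise DomainError(f"parameter_name must be 'beta' or 'h', got {parameter_name!r}")

    def crit(value: float) -> bool:
        p = params.replace(**{parameter_name: value})
        if criterion == "isogamy_destabilised":
            return _isogamy_destabilised(p)
        if criterion == "boundary_invadable":
            return _boundary_invadable(p, invasion_tol, grid_points)
        raise DomainError(f"unknown criterion {criterion!r}")

    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise DomainError(f"bracket must be increasing, got {bracket}")
    c_lo, c_hi = crit(lo), crit(hi)
    if c_lo == c_hi:
        raise NoSignChangeError(
            f"criterion {criterion!r} is {c_lo} at both ends of bracket {bracket}"
        )

    values = [lo, hi]
    regimes = [_regime_label(c_lo), _regime_label(c_hi)]
    iterations = 0
    while hi - lo > width:
        mid = 0.5 * (lo + hi)
        c_mid = crit(mid)
        values.append(mid)
        regimes.append(_regime_label(c_mid))
        if c_mid == c_lo:
            lo = mid
        else:
            hi = mid
        iterations += 1

    return ScanResult(
        parameter_name=parameter_name,
        values=tuple(values),
        regimes=tuple(regimes),
        critical_value=0.5 * (lo + hi),
        bracket=(lo, hi),
        iterations=iterations,
    )


def _regime_label(criterion_true: bool) -> str:
    return analytic.ANISOGAMY if criterion_true else analytic.ISOGAMY


def cutoff_free_critical_exponent(
    params: ModelParams,
    bracket: tuple[float, float],
    deltas: tuple[float, ...] = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8),
    width: float = BISECTION_WIDTH,
    grid_points: int = SCAN_GRID_POINTS,
) -> ExtrapolationResult:
    """Critical zygote-survival exponent in the vanishing-cutoff limit.

    The invasibility threshold detected against a ``(delta, delta)``
    resident is biased upward by ``O(1/ln(M/delta))`` for any finite
    viability cutoff; the structural condition on the power-law exponent
    does not involve the cutoff.  This runs the per-``delta`` bisection
    of :func:`find_threshold` over a decreasing ``delta`` sequence and
    extrapolates a quadratic polynomial in ``u = 1/ln(M/delta)`` to
    ``u = 0``.
    """
    scans = []
    values = []
    for d in deltas:
        p = params.replace(delta=d)
        scan = find_threshold(
            p,
            parameter_name="h",
            bracket=bracket,
            criterion="boundary_invadable",
            width=width,
            grid_points=grid_points,
        )
        scans.append(scan)
        values.append(scan.critical_value)
    u = 1.0 / np.log(params.M / np.asarray(deltas, dtype=float))
    deg = min(2, len(deltas) - 1)
    coeffs = np.polynomial.polynomial.polyfit(u, np.asarray(values), deg)
    return ExtrapolationResult(
        critical_value=float(coeffs[0]),
        deltas=tuple(float(d) for d in deltas),
        per_delta_values=tuple(values),
        scans=tuple(scans),
    )
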