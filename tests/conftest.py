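import math

import pytest
from hypothesis import settings

from anisogame import GameteSizePair, ModelParams, log_fitness

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def exp_params() -> ModelParams:
    """Exponential-survival model in the anisogamous regime (beta > 4*alpha)."""
    return ModelParams(M=100.0, alpha=1.0, beta=8.0)


@pytest.fixture
def iso_params() -> ModelParams:
    """Exponential-survival model in the isogamous regime (beta < 4*alpha)."""
    return ModelParams(M=100.0, alpha=1.0, beta=2.0)


@pytest.fixture
def power_params() -> ModelParams:
    """Threshold gamete survival with power-law zygote survival."""
    return ModelParams(
        M=1.0,
        k=1.0,
        c=1.0,
        h=1.5,
        delta=1e-3,
        gamete_survival_form="threshold",
        zygote_survival_form="power",
    )


def fd_gradient(point: GameteSizePair, params: ModelParams) -> tuple[float, float]:
    """Central finite-difference oracle for the log-fitness gradient."""

    def d(fn, at: float) -> float:
        h = 1e-6 * at
        return (fn(at + h) - fn(at - h)) / (2 * h)

    gx = d(lambda v: log_fitness(v, point.y, params), point.x)
    gy = d(lambda v: log_fitness(v, point.x, params), point.y)
    return gx, gy


def fd_jacobian(point: GameteSizePair, params: ModelParams):
    """Finite-difference oracle for the gradient-system Jacobian."""
    from anisogame import selection_gradient

    def col(idx: int):
        h = 1e-6 * (point.x if idx == 0 else point.y)
        up = [point.x, point.y]
        dn = [point.x, point.y]
        up[idx] += h
        dn[idx] -= h
        gu = selection_gradient(GameteSizePair(*up), params)
        gd = selection_gradient(GameteSizePair(*dn), params)
        return [(gu[0] - gd[0]) / (2 * h), (gu[1] - gd[1]) / (2 * h)]

    c0, c1 = col(0), col(1)
    return [[c0[0], c1[0]], [c0[1], c1[1]]]


def assert_close(a: float, b: float, tol: float = 1e-10) -> None:
    assert math.isclose(a, b, rel_tol=tol, abs_tol=tol), f"{a} != {b} (tol {tol})"
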