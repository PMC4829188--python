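"""Shared fixtures and independent quadrature oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

import chemopulse as cp
from chemopulse.profiles import Kernel, WaveProfile


@pytest.fixture(scope="session")
def params() -> cp.ModelParams:
    """Reference two-strain parameter set (CGS units)."""
    return cp.table1()


@pytest.fixture(scope="session")
def desk_run(params):
    """Single-species (slow strain only) desk-scale simulation.

    1.8 cm channel at 10 um resolution, 40 min horizon: long enough for the
    pulse to form and travel ~0.5 cm, shared by the speed/shape/field-sign
    checks.
    """
    p = params.with_phi(0.0)
    grid = cp.Grid(L=1.8, K=1800)
    cfg = cp.SchemeConfig(T=2400.0, save_every=50)
    return p, grid, cp.run(p, grid, cfg)


def quad_mass(profile: WaveProfile, i: int) -> float:
    """Adaptive-quadrature mass of one species' analytic pulse."""
    left = quad(lambda z: profile.rho(z, i), -np.inf, 0.0)[0]
    right = quad(lambda z: profile.rho(z, i), 0.0, np.inf)[0]
    return left + right


def quad_attractant(profile: WaveProfile, fields, z: float) -> float:
    """Adaptive-quadrature convolution ``S(z) = int K(z-y) rho_tot(y) dy``.

    The integrand kinks at ``y = 0`` (pulse peak) and ``y = z`` (kernel
    kink), so the real line is split there.
    """
    kernel = Kernel(sigma=profile.sigma, D_S=fields.D_S, alpha=fields.alpha)

    def f(y: float) -> float:
        return kernel(z - y) * float(profile.rho_total(y))

    tol = {"epsabs": 1e-14, "epsrel": 1e-12, "limit": 200}
    a, b = sorted((0.0, z))
    total = quad(f, -np.inf, a, **tol)[0]
    if b > a:
        total += quad(f, a, b, **tol)[0]
    total += quad(f, b, np.inf, **tol)[0]
    return total


def quad_attractant_slope_at_peak(profile: WaveProfile, fields) -> float:
    """Adaptive-quadrature ``S'(0) = int K'(x) rho_tot(-x) dx``."""
    kernel = Kernel(sigma=profile.sigma, D_S=fields.D_S, alpha=fields.alpha)
    mp, mm = kernel.mu_plus, kernel.mu_minus

    def kprime(x: float) -> float:
        if x >= 0.0:
            return -mp * np.exp(-mp * x)
        return mm * np.exp(mm * x)

    def f(x: float) -> float:
        return kprime(x) * float(profile.rho_total(-x))

    return quad(f, -np.inf, 0.0)[0] + quad(f, 0.0, np.inf)[0]
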