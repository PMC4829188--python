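"""Wave-speed equations: single-species root, mixed root, and the threshold.

A single species traveling alone moves at the unique speed solving
``chi^N - sigma = chi^S sigma / sqrt(4 D_S alpha + sigma^2)``.  A mixture
with fast fraction ``phi`` moves as one pulse at the speed solving
``g_1(sigma) + phi/(1-phi) H(sigma) g_2(sigma) = 0`` on the window
``Omega = (sigma_1, sigma_2) cap (I_1 cap I_2)`` — but only while ``phi``
stays at or below the critical fraction ``phi* = lam*/(1+lam*)``, where
``lam*`` is the maximum of ``G`` over the window.  Beyond ``phi*`` no
single-speed pulse exists and the two subpopulations travel separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import (
    ENDPOINT_MARGIN,
    FieldParams,
    ModelParams,
    SpeciesParams,
    SpeedInterval,
    _single_speed,
    big_G,
    big_H,
    g,
)

__all__ = [
    "DispersionResult",
    "ExistenceDiagnostics",
    "CriticalFraction",
    "single_species_speed",
    "existence_conditions",
    "admissible_interval",
    "two_species_speed",
    "mixed_speed_roots",
    "critical_fraction",
    "analyze",
]


@dataclass(frozen=True)
class ExistenceDiagnostics:
    """Outcome of the structural assumptions behind the mixed-pulse theory.

    The three clauses are: the admissible intervals overlap; the fast
    single-species speed lies outside the overlap; the left end of the fast
    interval lies outside the overlap.  When all hold, the realized speed
    window is exactly ``(sigma_1, chi_1^N + chi_1^S)``.
    """

    ok: bool
    overlap_nonempty: bool
    sigma2_outside: bool
    fast_left_end_outside: bool
    messages: tuple[str, ...] = ()


@dataclass(frozen=True)
class CriticalFraction:
    """Bifurcation threshold ``phi*`` and the associated maximizer of ``G``."""

    phi_star: float
    lambda_star: float
    sigma_at_max: float


@dataclass(frozen=True)
class DispersionResult:
    """Complete dispersion analysis at one population mix."""

    sigma1: float
    sigma2: float
    omega: SpeedInterval
    phi_red: float
    sigma_mix: Optional[float]
    exists: bool
    lambda_star: float
    phi_star: float
    roots: tuple[float, ...] = ()


def single_species_speed(species: SpeciesParams, fields: FieldParams) -> float:
    """Unique traveling speed of a species alone (cm/s).

    ``g`` is strictly increasing, negative at ``chi^N - chi^S`` and positive
    at ``chi^N + chi^S``, so the bracketed Brent solve always converges.
    """
    return _single_speed(species, fields)


def existence_conditions(params: ModelParams) -> ExistenceDiagnostics:
    """Check the assumptions under which the mixed-pulse analysis applies."""
    sp1, sp2 = params.species
    overlap = params.overlap()
    msgs: list[str] = []
    if overlap is None:
        return ExistenceDiagnostics(
            ok=False,
            overlap_nonempty=False,
            sigma2_outside=True,
            fast_left_end_outside=True,
            messages=("admissible intervals I_1 and I_2 are disjoint",),
        )
    sigma2 = single_species_speed(sp2, params.fields)
    s2_out = not overlap.contains(sigma2)
    if not s2_out:
        msgs.append("fast single-species speed sigma_2 lies inside I_1 cap I_2")
    left_out = not overlap.contains(sp2.chi_N - sp2.chi_S)
    if not left_out:
        msgs.append("left end of I_2 lies inside I_1 cap I_2")
    return ExistenceDiagnostics(
        ok=s2_out and left_out,
        overlap_nonempty=True,
        sigma2_outside=s2_out,
        fast_left_end_outside=left_out,
        messages=tuple(msgs),
    )


def admissible_interval(params: ModelParams) -> SpeedInterval:
    """Realized speed window ``Omega = (sigma_1, sigma_2) cap (I_1 cap I_2)``.

    Under the existence conditions this is ``(sigma_1, chi_1^N + chi_1^S)``.
    """
    diag = existence_conditions(params)
    if not diag.ok:
        raise ValueError(f"existence conditions violated: {diag.messages}")
    sigma1 = single_species_speed(params.species[0], params.fields)
    sigma2 = single_species_speed(params.species[1], params.fields)
    overlap = params.overlap()
    assert overlap is not None
    window = SpeedInterval(sigma1, sigma2).intersect(overlap)
    if window is None:  # pragma: no cover - excluded by the conditions above
        raise ValueError("speed window is empty")
    return window


def _residual(sigma: float, params: ModelParams, ratio: float) -> float:
    """Left side of the mixed dispersion relation, ``ratio = phi/(1-phi)``."""
    sp1, sp2 = params.species
    return g(sigma, sp1, params.fields) + ratio * big_H(sigma, params) * g(
        sigma, sp2, params.fields
    )


def mixed_speed_roots(
    params: ModelParams,
    phi_red: float,
    *,
    n_grid: int = 2048,
    margin: float = ENDPOINT_MARGIN,
) -> tuple[float, ...]:
    """All roots of the mixed dispersion relation on the speed window.

    The relation may admit more than one root for ``phi`` below the
    threshold (generically two, merging at ``phi*``); the window is scanned
    on ``n_grid`` points, every sign change is bracketed and polished with
    Brent's method.
    """
    if not 0.0 <= phi_red < 1.0:
        raise ValueError("phi_red must lie in [0, 1); phi_red = 1 is singular")
    window = admissible_interval(params).interior(margin)
    if phi_red == 0.0:
        return (single_species_speed(params.species[0], params.fields),)
    ratio = phi_red / (1.0 - phi_red)
    grid = np.linspace(window.lo, window.hi, n_grid)
    vals = np.array([_residual(s, params, ratio) for s in grid])
    roots: list[float] = []
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for k in sign_changes:
        root = brentq(
            _residual,
            grid[k],
            grid[k + 1],
            args=(params, ratio),
            xtol=1e-15,
            rtol=8.9e-16,
        )
        roots.append(float(root))
    return tuple(roots)


def two_species_speed(
    params: ModelParams,
    phi_red: float,
    *,
    n_grid: int = 2048,
) -> Optional[float]:
    """Common speed of the co-moving two-species pulse, or ``None``.

    Returns the root branch continuous from ``sigma(0) = sigma_1`` (the
    smallest root); ``None`` when ``phi_red`` exceeds the critical fraction
    and no single-speed pulse exists.
    """
    roots = mixed_speed_roots(params, phi_red, n_grid=n_grid)
    return roots[0] if roots else None


def critical_fraction(
    params: ModelParams,
    *,
    n_grid: int = 4096,
    margin: float = ENDPOINT_MARGIN,
) -> CriticalFraction:
    """Threshold fast fraction ``phi*`` above which the common pulse is lost.

    ``G`` is evaluated on a dense grid over the closed speed window (with a
    tiny endpoint margin); the grid maximum is refined by bounded scalar
    minimization of ``-G`` between its neighbors.  ``G`` vanishes at
    ``sigma_1`` and at the right end, so the maximum is interior.
    """
    diag = existence_conditions(params)
    if not diag.ok:
        raise ValueError(f"existence conditions violated: {diag.messages}")
    window = admissible_interval(params).interior(margin)
    grid = np.linspace(window.lo, window.hi, n_grid)
    vals = np.array([big_G(s, params) for s in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda s: -big_G(s, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-15},
    )
    lam = float(-res.fun)
    return CriticalFraction(
        phi_star=lam / (1.0 + lam), lambda_star=lam, sigma_at_max=float(res.x)
    )


def analyze(params: ModelParams, phi_red: float | None = None) -> DispersionResult:
    """Full dispersion analysis at the given (or stored) population mix."""
    phi = params.phi_red if phi_red is None else phi_red
    sigma1 = single_species_speed(params.species[0], params.fields)
    sigma2 = single_species_speed(params.species[1], params.fields)
    omega = admissible_interval(params)
    crit = critical_fraction(params)
    roots = mixed_speed_roots(params, phi)
    return DispersionResult(
        sigma1=sigma1,
        sigma2=sigma2,
        omega=omega,
        phi_red=phi,
        sigma_mix=roots[0] if roots else None,
        exists=bool(roots),
        lambda_star=crit.lambda_star,
        phi_star=crit.phi_star,
        roots=roots,
    )
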