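"""Seeded synthetic inputs: translating pulses, noisy profiles, tracks.

Every generator is a pure function of its arguments; randomness is drawn
from a stream derived from ``(seed, kind)`` so adding a new fixture kind
never perturbs existing ones.
"""

from __future__ import annotations

import warnings

import numpy as np

from .simulate import Grid, Kymograph

__all__ = [
    "make_translating_pulse",
    "make_noisy_profile",
    "make_linear_track",
    "double_exponential",
]

_KIND_CODES = {
    "translating_pulse": 1,
    "noisy_profile": 2,
    "linear_track": 3,
}


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _KIND_CODES[kind]])


def double_exponential(
    z: np.ndarray, lam_minus: float, lam_plus: float, rho_max: float = 1.0
) -> np.ndarray:
    """Asymmetric double-exponential pulse centered at ``z = 0``."""
    z = np.asarray(z, dtype=float)
    return rho_max * np.exp(np.where(z < 0.0, lam_minus * z, lam_plus * z))


def make_translating_pulse(
    grid: Grid,
    times: np.ndarray,
    speed: float,
    lam_minus: float,
    lam_plus: float,
    *,
    rho_max: float = 1.0,
    x0: float | None = None,
    species2: dict | None = None,
) -> Kymograph:
    """Analytic pulse advected rigidly at constant speed, frame by frame.

    ``species2``, when given, supplies ``speed``, ``lam_minus``,
    ``lam_plus`` (and optionally ``rho_max``, ``x0``) for a second,
    independently translating pulse — handy for exercising the split
    classifier.  Pulses are simply clipped at the closed boundaries; a
    warning is raised if a peak leaves the domain.
    """
    times = np.asarray(times, dtype=float)
    x = grid.x
    start = grid.L / 10.0 if x0 is None else x0

    def stack(v: float, lm: float, lp: float, rm: float, x_start: float) -> np.ndarray:
        centers = x_start + v * times
        if centers.max() > grid.L or centers.min() < 0.0:
            warnings.warn("pulse peak leaves the domain; frames are truncated")
        return np.stack(
            [double_exponential(x - c, lm, lp, rm) for c in centers]
        )

    rho1 = stack(speed, lam_minus, lam_plus, rho_max, start)
    if species2 is None:
        rho2 = np.zeros_like(rho1)
    else:
        rho2 = stack(
            species2["speed"],
            species2["lam_minus"],
            species2["lam_plus"],
            species2.get("rho_max", rho_max),
            species2.get("x0", start),
        )
    zeros = np.zeros_like(rho1)
    return Kymograph(
        times=times,
        x=x,
        rho1=rho1,
        rho2=rho2,
        S=zeros,
        N=zeros.copy(),
        dx=grid.dx,
        dt=float(times[1] - times[0]) if len(times) > 1 else 1.0,
    )


def make_noisy_profile(
    z: np.ndarray,
    lam_minus: float,
    lam_plus: float,
    *,
    rho_max: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Double exponential with multiplicative log-normal noise of level ``noise``.

    ``noise`` is the standard deviation of ``log rho``; zero noise returns
    the exact profile.
    """
    if noise < 0.0:
        raise ValueError("noise level must be >= 0")
    clean = double_exponential(z, lam_minus, lam_plus, rho_max)
    if noise == 0.0:
        return clean
    rng = _rng(seed, "noisy_profile")
    return clean * np.exp(noise * rng.standard_normal(len(clean)))


def make_linear_track(
    times: np.ndarray,
    speed: float,
    *,
    intercept: float = 0.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Positions on a line of the given slope with seeded Gaussian jitter."""
    times = np.asarray(times, dtype=float)
    pos = intercept + speed * times
    if jitter > 0.0:
        rng = _rng(seed, "linear_track")
        pos = pos + jitter * rng.standard_normal(len(times))
    return pos
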