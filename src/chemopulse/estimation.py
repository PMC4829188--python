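"""Invert pulse-shape observables into chemotactic parameters.

A traveling pulse carries its generating parameters in its shape: the flank
decay rates ``lam^- > 0 > lam^+`` and the speed ``sigma`` determine the
chemotactic sensitivities and the attractant degradation rate in closed
form::

    chi^S = D (lam^- - lam^+) / 2
    chi^N = sigma + D (lam^- + lam^+) / 2
    alpha = - sigma^2 lam^+ lam^- / ( D_S (lam^+ + lam^-)^2 )

(the alpha formula follows from eliminating chi^S, chi^N in the
single-species speed equation; it is undefined for a symmetric profile,
``lam^- = -lam^+``, where ``sigma = chi^N`` carries no information about
``alpha``).  ``fit_decay_rates`` supplies the flank rates from a sampled
profile by log-linear regression restricted to an amplitude window that
avoids both the rounded tip and the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

__all__ = [
    "ShapeObservables",
    "ChemotacticEstimate",
    "FlankFit",
    "invert_shape",
    "fit_decay_rates",
]


@dataclass(frozen=True)
class ShapeObservables:
    """Measured pulse shape: flank rates, speed, and known diffusivities."""

    lam_minus: float  # left decay rate (1/cm), > 0
    lam_plus: float  # right decay rate (1/cm), < 0
    sigma: float  # wave speed (cm/s)
    D: float  # bacterial diffusion (cm^2/s), measured
    D_S: float  # attractant diffusion (cm^2/s), literature value

    def __post_init__(self) -> None:
        if not self.lam_minus > 0.0 > self.lam_plus:
            raise ValueError("flank rates must satisfy lam^- > 0 > lam^+")
        if self.sigma <= 0.0:
            raise ValueError("wave speed must be > 0")
        if self.D <= 0.0 or self.D_S <= 0.0:
            raise ValueError("diffusivities must be > 0")


@dataclass(frozen=True)
class ChemotacticEstimate:
    chi_S: float
    chi_N: float
    alpha: float


@dataclass(frozen=True)
class FlankFit:
    """Log-linear flank rates with regression standard errors."""

    lam_minus: float
    lam_plus: float
    stderr_minus: float
    stderr_plus: float
    n_left: int
    n_right: int


def invert_shape(obs: ShapeObservables) -> ChemotacticEstimate:
    """Closed-form parameter inversion from one pulse's shape."""
    lsum = obs.lam_plus + obs.lam_minus
    if lsum == 0.0:
        raise ValueError(
            "symmetric profile (lam^- = -lam^+ means sigma = chi^N): "
            "alpha is not identifiable from the shape"
        )
    chi_S = obs.D * (obs.lam_minus - obs.lam_plus) / 2.0
    chi_N = obs.sigma + obs.D * lsum / 2.0
    alpha = -(obs.sigma**2) * obs.lam_plus * obs.lam_minus / (obs.D_S * lsum**2)
    return ChemotacticEstimate(chi_S=chi_S, chi_N=chi_N, alpha=alpha)


def fit_decay_rates(
    z: np.ndarray,
    rho: np.ndarray,
    *,
    window: tuple[float, float] = (0.10, 0.60),
    min_points: int = 5,
) -> FlankFit:
    """Flank decay rates of a sampled pulse by log-linear least squares.

    Points on each side of the peak whose amplitude lies in
    ``[window[0], window[1]]`` of the peak value enter a linear regression
    of ``log rho`` against ``z``; the slopes are ``lam^-`` (left) and
    ``lam^+`` (right).  Raises when either flank has fewer than
    ``min_points`` usable samples.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if z.shape != rho.shape or z.ndim != 1:
        raise ValueError("z and rho must be 1-D arrays of equal length")
    top = rho.max()
    if top <= 0.0:
        raise ValueError("profile has no positive values")
    k = int(np.argmax(rho))
    lo, hi = window[0] * top, window[1] * top
    in_band = (rho >= lo) & (rho <= hi) & (rho > 0.0)
    left = in_band & (np.arange(len(z)) < k)
    right = in_band & (np.arange(len(z)) > k)
    if left.sum() < min_points or right.sum() < min_points:
        raise ValueError(
            f"insufficient flank points (left={left.sum()}, right={right.sum()}, "
            f"need {min_points}); widen the window or refine the sampling"
        )
    fit_l = linregress(z[left], np.log(rho[left]))
    fit_r = linregress(z[right], np.log(rho[right]))
    return FlankFit(
        lam_minus=float(fit_l.slope),
        lam_plus=float(fit_r.slope),
        stderr_minus=float(fit_l.stderr),
        stderr_plus=float(fit_r.stderr),
        n_left=int(left.sum()),
        n_right=int(right.sum()),
    )
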