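"""Closed-form traveling-pulse profiles and the chemoattractant they shape.

In the frame ``z = x - sigma t`` each bacterial density is a double
asymmetric exponential peaked at ``z = 0``::

    rho_i(z) = rho_i^M exp(lam_i^- z)  (z < 0),
               rho_i^M exp(lam_i^+ z)  (z > 0),

    lam_i^- = (chi_i^N + chi_i^S - sigma) / D_i > 0,
    lam_i^+ = (chi_i^N - chi_i^S - sigma) / D_i < 0,

and the chemoattractant is the convolution ``S = K * (rho_1 + rho_2)`` with
the two-sided exponential Green's kernel

    K(z) = exp( -sigma z / (2 D_S) - sqrt(sigma^2 + 4 alpha D_S) |z| / (2 D_S) ).

The convolution is evaluated analytically segment by segment (each piece is
a sum of at most three exponentials); adaptive quadrature serves only as a
cross-check in the test suite.  The stationarity of ``S`` at the peak,
``S'(0) = 0``, is precisely the mixed dispersion relation; the residual
form exposed here vanishes iff ``sigma`` solves it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import FieldParams, ModelParams, SpeciesParams
from .dispersion import two_species_speed

__all__ = [
    "WaveProfile",
    "Kernel",
    "ChemoattractantProfile",
    "decay_rates",
    "peak_amplitude",
    "build_wave_profile",
    "chemoattractant_profile",
    "s_prime_zero_residual",
]


def decay_rates(sigma: float, species: SpeciesParams) -> tuple[float, float]:
    """Flank decay rates ``(lam^-, lam^+)`` of the pulse at speed ``sigma``.

    Raises ``ValueError`` when ``sigma`` falls outside the open admissible
    interval, where no two-sided decaying pulse exists.
    """
    lam_m = (species.chi_N + species.chi_S - sigma) / species.D
    lam_p = (species.chi_N - species.chi_S - sigma) / species.D
    if not (lam_m > 0.0 > lam_p):
        raise ValueError(
            f"speed sigma={sigma} outside the admissible interval "
            f"[{species.chi_N - species.chi_S}, {species.chi_N + species.chi_S}]: "
            "no traveling pulse"
        )
    return lam_m, lam_p


def peak_amplitude(mass: float, lam_minus: float, lam_plus: float) -> float:
    """Peak density from the total mass of the double exponential.

    ``integral rho = rho^M (1/lam^- - 1/lam^+)``, hence
    ``rho^M = M / (1/lam^- - 1/lam^+)``.
    """
    if mass <= 0.0:
        raise ValueError("subpopulation mass must be > 0")
    return mass / (1.0 / lam_minus - 1.0 / lam_plus)


@dataclass(frozen=True)
class WaveProfile:
    """Evaluable two-species traveling-pulse shape at a common speed."""

    sigma: float
    lam_minus: tuple[float, float]
    lam_plus: tuple[float, float]
    rho_max: tuple[float, float]

    def rho(self, z, i: int):
        """Density of species ``i`` (0 = slow, 1 = fast) at ``z`` (cm)."""
        z = np.asarray(z, dtype=float)
        return self.rho_max[i] * np.exp(
            np.where(z < 0.0, self.lam_minus[i] * z, self.lam_plus[i] * z)
        )

    def rho_total(self, z):
        return self.rho(z, 0) + self.rho(z, 1)

    def mass(self, i: int) -> float:
        return self.rho_max[i] * (1.0 / self.lam_minus[i] - 1.0 / self.lam_plus[i])


def build_wave_profile(
    params: ModelParams,
    phi_red: float | None = None,
    *,
    sigma: float | None = None,
) -> WaveProfile:
    """Assemble the analytic pulse for the given mix.

    The speed is the mixed dispersion root unless ``sigma`` is forced
    explicitly; masses come from the population mix.  Raises when no
    common pulse exists at this mix.
    """
    phi = params.phi_red if phi_red is None else phi_red
    if sigma is None:
        sigma = two_species_speed(params, phi)
        if sigma is None:
            raise ValueError(
                f"no single-speed traveling pulse at phi_red={phi} "
                "(above the critical fraction)"
            )
    total = params.mix.total
    masses = ((1.0 - phi) * total, phi * total)
    lam_m: list[float] = []
    lam_p: list[float] = []
    rho_m: list[float] = []
    for sp, M in zip(params.species, masses):
        lm, lp = decay_rates(sigma, sp)
        lam_m.append(lm)
        lam_p.append(lp)
        rho_m.append(peak_amplitude(M, lm, lp) if M > 0.0 else 0.0)
    return WaveProfile(
        sigma=float(sigma),
        lam_minus=tuple(lam_m),
        lam_plus=tuple(lam_p),
        rho_max=tuple(rho_m),
    )


@dataclass(frozen=True)
class Kernel:
    """Two-sided exponential kernel mapping total density to attractant."""

    sigma: float
    D_S: float
    alpha: float

    @property
    def root(self) -> float:
        return math.sqrt(self.sigma**2 + 4.0 * self.alpha * self.D_S)

    @property
    def mu_plus(self) -> float:
        """Decay rate of ``K`` for ``z > 0``; positive since ``root > |sigma|``."""
        return (self.root + self.sigma) / (2.0 * self.D_S)

    @property
    def mu_minus(self) -> float:
        """Decay rate of ``K`` for ``z < 0``."""
        return (self.root - self.sigma) / (2.0 * self.D_S)

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        return np.exp(np.where(z >= 0.0, -self.mu_plus * z, self.mu_minus * z))


class ChemoattractantProfile:
    """Closed-form ``S(z) = K * (rho_1 + rho_2)`` for a traveling pulse.

    For each species the convolution splits into exponential segments::

        z >= 0:  A e^{-mu+ z} + B e^{lam+ z}
        z <  0:  C e^{lam- z} + E e^{mu- z}

    with coefficients fixed by the partial-fraction denominators
    ``mu+ + lam-``, ``mu+ + lam+``, ``mu- - lam+`` and ``lam- - mu-``.
    The two denominators that may vanish (resonance of a flank rate with a
    kernel rate, a measure-zero parameter coincidence) are regularized by a
    relative machine-epsilon perturbation of the decay rate, with a warning.
    """

    def __init__(self, profile: WaveProfile, fields: FieldParams):
        self.profile = profile
        self.kernel = Kernel(sigma=profile.sigma, D_S=fields.D_S, alpha=fields.alpha)
        mp, mm = self.kernel.mu_plus, self.kernel.mu_minus
        self._terms = []  # per species: (A, B, C, E, lam_m, lam_p)
        for i in range(2):
            rM = profile.rho_max[i]
            if rM == 0.0:
                self._terms.append((0.0, 0.0, 0.0, 0.0, 1.0, -1.0))
                continue
            lm, lp = profile.lam_minus[i], profile.lam_plus[i]
            scale = max(abs(lp), mp)
            if abs(mp + lp) < 64.0 * np.finfo(float).eps * scale:
                warnings.warn(
                    "resonance lam^+ = -mu^+ in the attractant convolution; "
                    "perturbing the decay rate by machine epsilon"
                )
                lp -= 256.0 * np.finfo(float).eps * scale
            scale = max(lm, mm)
            if abs(lm - mm) < 64.0 * np.finfo(float).eps * scale:
                warnings.warn(
                    "resonance lam^- = mu^- in the attractant convolution; "
                    "perturbing the decay rate by machine epsilon"
                )
                lm += 256.0 * np.finfo(float).eps * scale
            A = rM * (1.0 / (mp + lm) - 1.0 / (mp + lp))
            B = rM * (1.0 / (mp + lp) + 1.0 / (mm - lp))
            C = rM * (1.0 / (mp + lm) - 1.0 / (lm - mm))
            E = rM * (1.0 / (lm - mm) + 1.0 / (mm - lp))
            self._terms.append((A, B, C, E, lm, lp))

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        mp, mm = self.kernel.mu_plus, self.kernel.mu_minus
        out = np.zeros_like(z)
        pos = z >= 0.0
        for A, B, C, E, lm, lp in self._terms:
            right = A * np.exp(-mp * z) + B * np.exp(lp * z)
            left = C * np.exp(lm * z) + E * np.exp(mm * z)
            out = out + np.where(pos, right, left)
        return out

    def derivative(self, z):
        """Analytic ``S'(z)`` (one-sided limits coincide at ``z = 0``)."""
        z = np.asarray(z, dtype=float)
        mp, mm = self.kernel.mu_plus, self.kernel.mu_minus
        out = np.zeros_like(z)
        pos = z >= 0.0
        for A, B, C, E, lm, lp in self._terms:
            right = -mp * A * np.exp(-mp * z) + lp * B * np.exp(lp * z)
            left = lm * C * np.exp(lm * z) + mm * E * np.exp(mm * z)
            out = out + np.where(pos, right, left)
        return out


def chemoattractant_profile(
    profile: WaveProfile, fields: FieldParams
) -> ChemoattractantProfile:
    """Closed-form attractant profile driven by the two density pulses."""
    return ChemoattractantProfile(profile, fields)


def s_prime_zero_residual(
    sigma: float, params: ModelParams, phi_red: float
) -> float:
    """Peak-stationarity residual ``S'(0)`` as a function of trial speed.

    Assembled from the left/right kernel half-integrals with the peak
    amplitudes fixed by mass normalization (unit total mass; the residual
    scales linearly with total mass).  Vanishes exactly when ``sigma``
    solves the mixed dispersion relation, and is proportional to its left
    side by a positive factor, so its sign flips across the root.
    """
    fields = params.fields
    R = math.sqrt(sigma * sigma + 4.0 * fields.alpha * fields.D_S)
    DS = fields.D_S
    masses = (1.0 - phi_red, phi_red)
    out = 0.0
    for sp, M in zip(params.species, masses):
        if M == 0.0:
            continue
        lm, lp = decay_rates(sigma, sp)
        rM = peak_amplitude(M, lm, lp)
        s_minus = rM * (-sigma + R) / (-sigma + R - 2.0 * DS * lp)
        s_plus = rM * (sigma + R) / (-sigma - R - 2.0 * DS * lm)
        out += s_minus + s_plus
    return out
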