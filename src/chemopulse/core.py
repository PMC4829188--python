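"""Model parameters and the scalar building blocks of the dispersion analysis.

The model describes two subpopulations of chemotactic bacteria (densities
``rho_1``, ``rho_2``) advancing in a 1-D channel, coupled through a
self-produced chemoattractant ``S`` and a consumed nutrient ``N``::

    d_t rho_i = D_i Lap rho_i - d_x( rho_i (u_i[S] + u_i[N]) )
    d_t S     = D_S Lap S - alpha S + rho_1 + rho_2
    d_t N     = D_N Lap N - gamma_1 rho_1 N - gamma_2 rho_2 N

with stiff chemotactic responses ``u_i[S] = chi_i^S sgn(d_x S)`` and
``u_i[N] = chi_i^N sgn(d_x N)``.  A traveling pulse of speed ``sigma``
exists for species ``i`` only if ``sigma`` lies strictly inside the
admissible interval ``I_i = [chi_i^N - chi_i^S, chi_i^N + chi_i^S]``.

This module owns the parameter containers and the four scalar functions
``g_i``, ``h_i``, ``H`` and ``G`` on which the traveling-wave layer is
built:

* ``g(sigma)  = (sigma - chi^N) + chi^S sigma / sqrt(sigma^2 + 4 alpha D_S)``
  is strictly increasing; its unique zero is the single-species wave speed.
* ``h(sigma)`` is a negative polynomial-plus-root expression entering the
  coupling weight; it is (up to the positive factor ``4 D_S / D_i``) the
  product ``(-sigma - R - 2 D_S lam^-)(-sigma + R - 2 D_S lam^+)`` with
  ``R = sqrt(sigma^2 + 4 alpha D_S)`` and ``lam^+-`` the pulse decay rates.
* ``H(sigma) > 0`` weights the fast species' contribution in the mixed
  dispersion relation ``g_1 + phi/(1-phi) H g_2 = 0``.
* ``G(sigma) = -g_1 / (H g_2)`` recast so that the relation reads
  ``G(sigma) = phi/(1-phi)``; the maximum of ``G`` over the admissible
  speed window yields the bifurcation threshold ``phi* = lam*/(1+lam*)``.

Internal units are CGS (cm, s) throughout; the reporting layer converts
speeds to um/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "SpeciesParams",
    "FieldParams",
    "PopulationMix",
    "ModelParams",
    "SpeedInterval",
    "CM_S_TO_UM_S",
    "ENDPOINT_MARGIN",
    "g",
    "h",
    "h_factored",
    "big_H",
    "big_G",
]

#: Conversion factor from cm/s to um/s for reported speeds.
CM_S_TO_UM_S = 1.0e4

#: Default relative margin kept away from singular interval endpoints.
ENDPOINT_MARGIN = 1.0e-9


@dataclass(frozen=True)
class SpeedInterval:
    """Closed speed interval ``[lo, hi]`` (cm/s)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"empty speed interval [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, sigma: float, *, open: bool = False) -> bool:
        if open:
            return self.lo < sigma < self.hi
        return self.lo <= sigma <= self.hi

    def interior(self, margin: float = ENDPOINT_MARGIN) -> "SpeedInterval":
        """Shrink both ends by ``margin`` times the width."""
        eps = margin * self.width
        return SpeedInterval(self.lo + eps, self.hi - eps)

    def intersect(self, other: "SpeedInterval") -> Optional["SpeedInterval"]:
        lo, hi = max(self.lo, other.lo), min(self.hi, other.hi)
        if lo >= hi:
            return None
        return SpeedInterval(lo, hi)


@dataclass(frozen=True)
class SpeciesParams:
    """Constants of one bacterial subpopulation.

    Parameters
    ----------
    D : float
        Effective bacterial diffusion coefficient (cm^2/s).
    chi_S : float
        Chemotactic sensitivity to the self-produced attractant (cm/s).
    chi_N : float
        Chemotactic sensitivity to the nutrient (cm/s).
    gamma : float
        Nutrient consumption rate (per unit density, rescaled model units).
        Does not enter the wave-speed theory; only the simulator uses it.
    """

    D: float
    chi_S: float
    chi_N: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("bacterial diffusion D must be > 0")
        if self.chi_S < 0 or self.chi_N < 0:
            raise ValueError("chemotactic sensitivities must be >= 0")
        if self.gamma < 0:
            raise ValueError("nutrient consumption rate gamma must be >= 0")

    def interval(self) -> SpeedInterval:
        """Admissible pulse-speed interval ``I = [chi_N - chi_S, chi_N + chi_S]``."""
        return SpeedInterval(self.chi_N - self.chi_S, self.chi_N + self.chi_S)


@dataclass(frozen=True)
class FieldParams:
    """Constants of the chemical fields.

    ``D_S``/``D_N`` are attractant/nutrient diffusivities (cm^2/s), ``alpha``
    the attractant degradation rate (1/s).
    """

    D_S: float
    D_N: float
    alpha: float

    def __post_init__(self) -> None:
        if self.D_S <= 0 or self.D_N <= 0:
            raise ValueError("chemical diffusivities must be > 0")
        if self.alpha <= 0:
            raise ValueError("degradation rate alpha must be > 0")


@dataclass(frozen=True)
class PopulationMix:
    """Total masses of the slow (``M1``) and fast (``M2``) subpopulations.

    ``phi_red = M2 / (M1 + M2)`` is the fraction of the fast (red)
    subpopulation; the wave-speed theory depends on the mix only through it.
    """

    M1: float
    M2: float

    def __post_init__(self) -> None:
        if self.M1 < 0 or self.M2 < 0 or self.M1 + self.M2 <= 0:
            raise ValueError("masses must be >= 0 with positive total")

    @property
    def total(self) -> float:
        return self.M1 + self.M2

    @property
    def phi_red(self) -> float:
        return self.M2 / (self.M1 + self.M2)

    @classmethod
    def from_phi(cls, phi_red: float, total: float = 1.0e-3) -> "PopulationMix":
        if not 0.0 <= phi_red <= 1.0:
            raise ValueError("phi_red must lie in [0, 1]")
        return cls(M1=(1.0 - phi_red) * total, M2=phi_red * total)


def _single_speed(species: SpeciesParams, fields: FieldParams) -> float:
    """Unique zero of ``g`` on the admissible interval (Brent's method)."""
    from scipy.optimize import brentq

    if species.chi_S == 0.0:
        return species.chi_N
    lo, hi = species.chi_N - species.chi_S, species.chi_N + species.chi_S
    return float(
        brentq(lambda s: g(s, species, fields), lo, hi, xtol=1e-15, rtol=8.9e-16)
    )


@dataclass(frozen=True)
class ModelParams:
    """Full two-species parameter set.

    ``species[0]`` is the slow subpopulation (green, speed ``sigma_1``) and
    ``species[1]`` the fast one (red, ``sigma_2``).  The ordering is checked
    at construction and the pair is silently re-indexed (masses swapped
    alongside) if it is violated.
    """

    species: tuple[SpeciesParams, SpeciesParams]
    fields: FieldParams
    mix: PopulationMix

    def __post_init__(self) -> None:
        s1 = _single_speed(self.species[0], self.fields)
        s2 = _single_speed(self.species[1], self.fields)
        if s1 > s2:
            object.__setattr__(self, "species", (self.species[1], self.species[0]))
            object.__setattr__(self, "mix", PopulationMix(self.mix.M2, self.mix.M1))

    @property
    def slow(self) -> SpeciesParams:
        return self.species[0]

    @property
    def fast(self) -> SpeciesParams:
        return self.species[1]

    @property
    def phi_red(self) -> float:
        return self.mix.phi_red

    def with_phi(self, phi_red: float, total: float | None = None) -> "ModelParams":
        """Same physics with the population mix replaced by ``phi_red``."""
        tot = self.mix.total if total is None else total
        return replace(self, mix=PopulationMix.from_phi(phi_red, tot))

    def overlap(self) -> Optional[SpeedInterval]:
        """Intersection ``I_1 cap I_2`` of the two admissible intervals."""
        return self.species[0].interval().intersect(self.species[1].interval())


def g(sigma: float, species: SpeciesParams, fields: FieldParams) -> float:
    """Single-species dispersion function, strictly increasing in ``sigma``.

    ``g(sigma) = (sigma - chi^N) + chi^S sigma / sqrt(sigma^2 + 4 alpha D_S)``.
    Its zero is the unique traveling speed of the species alone; ``g < 0``
    at the left end of ``I`` and ``g > 0`` at the right end, so the root is
    always bracketed.
    """
    root = math.sqrt(sigma * sigma + 4.0 * fields.alpha * fields.D_S)
    return (sigma - species.chi_N) + species.chi_S * sigma / root


def h(sigma: float, species: SpeciesParams, fields: FieldParams) -> float:
    """Coupling weight ``h(sigma)``; negative for ``sigma`` interior to ``I``.

    ``h = sigma^2 (D_S/D - 1) + (1 - 2 D_S/D) sigma chi^N
    - chi^S sqrt(sigma^2 + 4 alpha D_S)
    + (D_S/D)((chi^N)^2 - (chi^S)^2) - alpha D``.
    """
    r = fields.D_S / species.D
    root = math.sqrt(sigma * sigma + 4.0 * fields.alpha * fields.D_S)
    return (
        sigma * sigma * (r - 1.0)
        + (1.0 - 2.0 * r) * sigma * species.chi_N
        - species.chi_S * root
        + r * (species.chi_N**2 - species.chi_S**2)
        - fields.alpha * species.D
    )


def h_factored(sigma: float, species: SpeciesParams, fields: FieldParams) -> float:
    """Factorized form of the coupling weight; equals ``(4 D_S / D) h``.

    ``(-sigma - R - 2 D_S lam^-)(-sigma + R - 2 D_S lam^+)`` with
    ``R = sqrt(sigma^2 + 4 alpha D_S)`` and the pulse decay rates
    ``lam^- = (chi^N + chi^S - sigma)/D``, ``lam^+ = (chi^N - chi^S - sigma)/D``.
    For ``sigma`` interior to ``I`` the first factor is negative and the
    second positive, hence the product is negative.
    """
    root = math.sqrt(sigma * sigma + 4.0 * fields.alpha * fields.D_S)
    lam_m = (species.chi_N + species.chi_S - sigma) / species.D
    lam_p = (species.chi_N - species.chi_S - sigma) / species.D
    return (-sigma - root - 2.0 * fields.D_S * lam_m) * (
        -sigma + root - 2.0 * fields.D_S * lam_p
    )


def big_H(sigma: float, params: ModelParams) -> float:
    """Coupling ratio ``H(sigma) > 0`` of the two-species dispersion relation.

    ``H = (chi_1^S D_1)/(chi_2^S D_2)
    * [ (chi_2^S)^2 - (sigma - chi_2^N)^2 ] / [ (chi_1^S)^2 - (sigma - chi_1^N)^2 ]
    * h_1(sigma) / h_2(sigma)``.

    The mixed relation is ``g_1 + phi/(1-phi) H g_2 = 0``; ``H`` arises from
    eliminating the peak-amplitude ratio ``rho_2^M / rho_1^M`` through the
    mass normalization of the two pulse profiles.

    Raises
    ------
    ZeroDivisionError style ``ValueError`` when ``sigma`` sits at an
    endpoint of ``I_1`` where the squared-difference factor vanishes.
    """
    sp1, sp2 = params.species
    d1 = sp1.chi_S**2 - (sigma - sp1.chi_N) ** 2
    d2 = sp2.chi_S**2 - (sigma - sp2.chi_N) ** 2
    if d1 == 0.0:
        raise ValueError(
            f"H(sigma) singular: sigma={sigma} is an endpoint of the slow "
            "species' admissible interval"
        )
    pref = (sp1.chi_S * sp1.D) / (sp2.chi_S * sp2.D)
    return pref * (d2 / d1) * h(sigma, sp1, params.fields) / h(sigma, sp2, params.fields)


def big_G(sigma: float, params: ModelParams) -> float:
    """Bifurcation function ``G(sigma) = -g_1 / (H g_2)``, written pole-free.

    On the admissible window ``G >= 0`` with ``G(sigma_1) = 0``; where
    ``G(sigma) = phi/(1-phi)`` the mixed dispersion relation has a root, so
    the finite maximum ``lam* = max G`` gives the critical fast fraction
    ``phi* = lam*/(1 + lam*)``.

    The implementation expands ``-g_1/(H g_2)`` so the factor that makes
    ``H`` blow up at the right endpoint of ``I_1`` appears in the numerator,
    keeping ``G`` continuous (and zero) there.
    """
    sp1, sp2 = params.species
    d1 = sp1.chi_S**2 - (sigma - sp1.chi_N) ** 2
    d2 = sp2.chi_S**2 - (sigma - sp2.chi_N) ** 2
    pref = (sp2.chi_S * sp2.D) / (sp1.chi_S * sp1.D)
    return (
        -pref
        * (g(sigma, sp1, params.fields) / g(sigma, sp2, params.fields))
        * (h(sigma, sp2, params.fields) / h(sigma, sp1, params.fields))
        * (d1 / d2)
    )
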