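# Methods

## Model

Two subpopulations of chemotactic bacteria with densities ρ₁(x,t), ρ₂(x,t)
migrate along a closed 1-D channel, coupled through a chemoattractant S they
all produce and a nutrient N they all consume:

    ∂t ρᵢ = Dᵢ ∂xx ρᵢ − ∂x( ρᵢ (uᵢ[S] + uᵢ[N]) ),     i = 1, 2
    ∂t S  = D_S ∂xx S − α S + ρ₁ + ρ₂
    ∂t N  = D_N ∂xx N − γ₁ ρ₁ N − γ₂ ρ₂ N

with stiff chemotactic responses uᵢ[S] = χᵢ^S sgn(∂x S) and
uᵢ[N] = χᵢ^N sgn(∂x N). The sign-function response encodes a fast,
saturated reaction to gradients and is what makes the traveling-wave layer
fully solvable in closed form. Species 1 is the slow (green) strain, species
2 the fast (red) one; φ_red = M₂/(M₁+M₂) is the fast mass fraction. Internal
units are CGS (cm, s); reported speeds are converted to µm/s (×10⁴).

## Traveling-wave layer

In the frame z = x − σt a pulse of species i is a double asymmetric
exponential with rates λᵢ⁻ = (χᵢ^N + χᵢ^S − σ)/Dᵢ > 0 and
λᵢ⁺ = (χᵢ^N − χᵢ^S − σ)/Dᵢ < 0, which requires σ to lie strictly inside
Iᵢ = [χᵢ^N − χᵢ^S, χᵢ^N + χᵢ^S]. Peak amplitudes follow from mass
conservation, ∫ρᵢ = ρᵢ^M (1/λᵢ⁻ − 1/λᵢ⁺) (we use this quadrature-verified
normalization throughout; only the amplitude *ratio* enters the dispersion
relation, so any overall convention cancels there). The attractant is the
convolution S = K ∗ (ρ₁+ρ₂) with the two-sided exponential kernel
K(z) = exp(−σz/2D_S − √(σ²+4αD_S)|z|/2D_S); we evaluate it analytically
per exponential segment (partial fractions), keeping adaptive quadrature
only as a test oracle. The two denominators that can vanish (a flank rate
resonating with a kernel rate — a measure-zero parameter coincidence) are
regularized by a machine-epsilon perturbation with a warning.

Stationarity of S at the density peak, S′(0) = 0, yields the dispersion
relations:

* single species: χ^N − σ = χ^S σ/√(σ² + 4D_S α), with a unique root σᵢ in
  Iᵢ because the residual g(σ) = (σ−χ^N) + χ^S σ/√(σ²+4αD_S) is strictly
  increasing and changes sign across Iᵢ;
* mixture: g₁(σ) + [φ/(1−φ)] H(σ) g₂(σ) = 0 on the window
  Ω = (σ₁, σ₂) ∩ (I₁∩I₂), where H > 0 collects the amplitude-ratio and
  coupling weights (functions h₁, h₂ < 0 on the interior). Recast as
  G(σ) = φ/(1−φ) with G = −g₁/(H g₂) ≥ 0, the relation has roots exactly
  while φ/(1−φ) stays below λ* = max_Ω G; the critical fast fraction is
  φ* = λ*/(1+λ*). For the bundled strain parameters: σ₁ = 2.447 µm/s,
  σ₂ = 3.893 µm/s, λ* = 0.6370, φ* = 38.91% (argmax σ = 2.936 µm/s).

The root solver scans Ω on a 2048-point grid, brackets every sign change,
polishes with Brent's method (tolerance 10⁻¹⁵ on σ, i.e. ~10⁻¹¹ µm/s, far
below physical resolution) and returns the branch continuous from
σ(0) = σ₁ — the smallest root; generically a second root exists and the two
merge at φ*. λ* is located by a 4096-point scan plus bounded golden-section
refinement; interval endpoints, where H is singular, are avoided by a
relative margin of 10⁻⁹ of the window width.

## Numerical scheme

The simulator uses the semi-implicit splitting natural for this system:
implicit (tridiagonal) treatment of all diffusion and linear reaction
terms, explicit first-order upwind finite-volume advection with interface
fluxes F_{k+1/2} = a_k⁺ ρ_k − a_{k+1}⁻ ρ_{k+1} built from one-sided
gradient signs (sgn(0) = 0, so flat regions and exact extrema advect
nothing). Within a step, densities advance first, then the attractant
(driven by the new densities, decay implicit), then the nutrient
(consumption implicit in N, explicit in the pre-step densities). The time
step obeys only the advective CFL bound dt ≤ cfl·dx/maxᵢ(χᵢ^S+χᵢ^N)
(cfl = 0.9 by default). The closed channel is modeled with zero-flux
boundaries for all four fields; the flux-difference form telescopes, so
each species' discrete mass is conserved to solver round-off (measured:
<10⁻¹⁵ relative per step), and upwinding plus the implicit M-matrix
diffusion keeps all fields nonnegative.

Default desk scale: L = 1.8 cm (the experimental channel), K = 1800 cells
(dx = 10 µm, resolving flank widths of 60–600 µm), T = 3600 s. The scheme is
first order: measured front-speed error versus the analytic root is −4.4%
at dx = 40 µm, −2.3% at 20 µm, −1.2% at 10 µm.

## Initial condition and unspecified constants

The generator emulates the centrifugation protocol: all bacteria piled
against the left wall as an exponential profile (decay length L/50),
nutrient uniform at N₀, no attractant. γ₁ = γ₂ = 1 and N₀ = 1 in rescaled
units, with total mass M₁+M₂ = 10⁻³ chosen once so that γ·M_tot/σ ≈ 4: the
nutrient is then consumed on the pulse-transit timescale, producing the
sharp monotone nutrient front the traveling-wave ansatz assumes. None of
these constants enters the dispersion relation, so wave speeds are
insensitive to the choice; only the sharpness of the N front (and hence the
transient length) depends on it.

## Pulse analysis

Pulse position is the per-frame density argmax with parabolic sub-cell
refinement (ties resolve leftmost and are flagged); speed is the
least-squares slope after discarding the first 30% of frames (configurable)
— the pulse needs time to form and detach from the wall. A two-species run
is classified *split* when the peak separation exceeds 2× the mean pulse
FWHM throughout the final 20% of frames and still grows across that window;
the scale-free width unit makes the rule robust to grid choice.

## Shape inversion

Flank rates are fitted by log-linear regression restricted to amplitudes in
[10%, 60%] of the peak (defaults; the window avoids the rounded tip and the
noise floor). The closed-form inversion is χ^S = D(λ⁻−λ⁺)/2,
χ^N = σ + D(λ⁻+λ⁺)/2 and α = −σ²λ⁺λ⁻/(D_S(λ⁺+λ⁻)²); the α formula follows
from eliminating χ^S, χ^N in the single-species speed equation and is
undefined for a symmetric profile (λ⁻ = −λ⁺ forces σ = χ^N and α drops
out). The full loop parameters → σ → λ± → inversion is exact to 10⁻¹⁰ for
both bundled strains.

## Asymptotic threshold versus finite-time separation

Just above φ* no single-speed pulse exists, but the simulator (like the
experiment) shows a long-lived co-moving transient: the two populations
share one attractant peak and drift apart only slowly. Consequently the
*observed* separation threshold at any finite horizon sits above the
analytic φ* = 38.9% and creeps down as the horizon grows — we measure the
empirical split in (0.5, 0.6] at L = 7.2 cm, T = 14 400 s, and in
(0.42, 0.5] at L = 14.4 cm, T = 43 200 s, with the 2×FWHM classifier. This
reconciles the analytic threshold with separation being observed "around
50%" in channel-scale runs: the gap is metastability, not discretization
(recomputing φ* with upwind-diffusion-corrected coefficients moves it by
under 0.3% relative). At the 1.8 cm / 1200 s desk scale no composition
splits at all — the co-moving transient outlives the channel.

## Synthetic fixtures and what passing tests show

Fixtures provide exact translating double-exponential pulses, log-normal
multiplicative noisy profiles, and jittered linear tracks, all pure
functions of (arguments, seed) with per-kind RNG streams. They validate the
trackers and estimators against known ground truth; they do not emulate
fluorescence imaging (optics, bleaching, channel-switching lag), crowding
effects, or the altered medium behind a passed wave, so agreement on
fixtures and on the simulator bounds algorithmic error only — fidelity to
real kymographs remains qualitative.

## Known limitations

- First-order upwinding adds numerical diffusion ~|a|dx/2; flank-rate
  estimates from simulated profiles are biased low by up to ~8% at
  dx = 10 µm (within the 10% tolerance used in tests).
- Behind the wave the nutrient flattens to numerical round-off, so the
  discrete gradient sign vanishes there and a sub-percent residual density
  bump forms; field-sign checks therefore restrict to the pulse core
  (density ≥ 5% of peak).
- The dispersion solver certifies roots found by a dense scan; uniqueness
  beyond the scan resolution is empirical, not proven.
- No 2-D channel cross-section; no vanishing-diffusion (measure-solution)
  regime.
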