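"""Aerosol transport physics for the nanoparticle single-breath method.

Everything downstream — the instrument penetration model, the forward lung
simulator and the synthetic-data generator — rests on three ingredients
implemented here:

* slip-corrected Stokes–Einstein diffusion coefficients for 1 nm – 1 µm
  particles in air (the only transport property that matters for sub-100 nm
  aerosol at respiratory flows: no sedimentation or impaction terms),
* the eigenfunction series for the fraction of particles still airborne in a
  spherical cavity with perfectly absorbing walls (the distal-airspace
  deposition kernel), and
* the Gormley–Kennedy penetration of a laminar tube flow (conducting-airway
  and instrument-tubing losses).

Gas properties (viscosity, mean free path) are scaled from reference values
at 23 °C and 101.325 kPa with the Sutherland temperature law.  Two canonical
condition sets are exported: ``INSTRUMENT_CONDITIONS`` (the 35 °C heated box
that houses the flow meter, valve and sample collector) and
``BODY_CONDITIONS`` (37 °C lung air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GasConditions",
    "ParticleSpec",
    "DiffusionCoefficient",
    "INSTRUMENT_CONDITIONS",
    "BODY_CONDITIONS",
    "mean_free_path",
    "dynamic_viscosity",
    "cunningham_slip_factor",
    "diffusion_coefficient",
    "sphere_remaining_fraction",
    "tube_penetration",
    "gormley_kennedy_penetration",
]

BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)

#: Reference state for gas-property scaling: 23 °C, 101.325 kPa.
T_REFERENCE = 296.15  # K
P_REFERENCE = 101325.0  # Pa
VISCOSITY_REFERENCE = 1.83245e-5  # Pa s, air
MEAN_FREE_PATH_REFERENCE = 67.3e-9  # m, air
SUTHERLAND_CONSTANT = 110.4  # K

#: Davies slip-correction coefficients (the common aerosol-science default).
SLIP_COEFFICIENTS = (1.257, 0.400, 1.100)


class PhysicsValidationError(ValueError):
    """Raised for non-physical inputs (negative sizes, temperatures, ...)."""


def dynamic_viscosity(temperature: float) -> float:
    """Dynamic viscosity of air (Pa s) via Sutherland's law."""
    if temperature <= 0:
        raise PhysicsValidationError(f"temperature must be > 0 K, got {temperature}")
    t = temperature
    return (
        VISCOSITY_REFERENCE
        * (t / T_REFERENCE) ** 1.5
        * (T_REFERENCE + SUTHERLAND_CONSTANT)
        / (t + SUTHERLAND_CONSTANT)
    )


@dataclass(frozen=True)
class GasConditions:
    """Carrier-gas state; derived viscosity and mean free path are properties.

    Defaults to the instrument's heated box (35 °C, 1 atm).
    """

    temperature: float = 308.15  # K
    pressure: float = 101325.0  # Pa

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise PhysicsValidationError(f"temperature must be > 0, got {self.temperature}")
        if not (self.pressure > 0 and math.isfinite(self.pressure)):
            raise PhysicsValidationError(f"pressure must be > 0, got {self.pressure}")

    @property
    def dynamic_viscosity(self) -> float:
        return dynamic_viscosity(self.temperature)

    @property
    def mean_free_path(self) -> float:
        return mean_free_path(self)


INSTRUMENT_CONDITIONS = GasConditions(temperature=308.15)  # 35 °C heated box
BODY_CONDITIONS = GasConditions(temperature=310.15)  # 37 °C lung air


def mean_free_path(conditions: GasConditions) -> float:
    """Mean free path of air molecules (m) at the given conditions.

    Scaled from the 23 °C / 101.325 kPa reference value:
    lambda ∝ (T/P) × (1 + S/T_ref)/(1 + S/T), the standard hard-sphere /
    Sutherland correction.  Doubling the pressure at fixed temperature halves
    the result.
    """
    t, p = conditions.temperature, conditions.pressure
    return (
        MEAN_FREE_PATH_REFERENCE
        * (t / T_REFERENCE)
        * (P_REFERENCE / p)
        * (1.0 + SUTHERLAND_CONSTANT / T_REFERENCE)
        / (1.0 + SUTHERLAND_CONSTANT / t)
    )


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse test particle.

    The charge state (+1 downstream of the mobility classifier) is recorded
    for provenance but plays no role in transport: image-charge deposition is
    negligible for these sizes and materials.
    """

    diameter: float  # m
    nominal_label: str | None = None
    charge_state: int = 1

    def __post_init__(self) -> None:
        if not (1e-9 <= self.diameter <= 1e-6):
            raise PhysicsValidationError(
                "diameter must lie in the diffusion-dominated regime "
                f"[1 nm, 1 um], got {self.diameter} m"
            )

    @classmethod
    def from_nm(cls, diameter_nm: float, charge_state: int = 1) -> "ParticleSpec":
        return cls(
            diameter=diameter_nm * 1e-9,
            nominal_label=f"{diameter_nm:g} nm",
            charge_state=charge_state,
        )

    @property
    def diameter_nm(self) -> float:
        # divide by the same constant from_nm multiplies with, so
        # from_nm(x).diameter_nm round-trips exactly
        return self.diameter / 1e-9


#: The four nominal polystyrene-latex sizes used to characterize the method.
NOMINAL_SIZES_NM = (22.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class DiffusionCoefficient:
    value: float  # m^2/s
    particle: ParticleSpec
    conditions: GasConditions = field(default_factory=GasConditions)

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise PhysicsValidationError(f"diffusion coefficient must be > 0, got {self.value}")

    def __float__(self) -> float:
        return self.value


def cunningham_slip_factor(diameter: float, conditions: GasConditions | None = None) -> float:
    """Cunningham slip correction Cc(d) >= 1 with Davies coefficients.

    Cc = 1 + Kn (a + b exp(-c/Kn)), Kn = 2 lambda / d.  Approaches 1 in the
    continuum limit (large particles) and grows monotonically with Knudsen
    number.
    """
    if conditions is None:
        conditions = GasConditions()
    if not (diameter > 0 and math.isfinite(diameter)):
        raise PhysicsValidationError(f"diameter must be > 0, got {diameter}")
    a, b, c = SLIP_COEFFICIENTS
    kn = 2.0 * mean_free_path(conditions) / diameter
    return 1.0 + kn * (a + b * math.exp(-c / kn))


def diffusion_coefficient(
    particle: ParticleSpec | float, conditions: GasConditions | None = None
) -> DiffusionCoefficient:
    """Slip-corrected Stokes–Einstein diffusion coefficient.

    D = k T Cc / (3 pi mu d).  Accepts a :class:`ParticleSpec` or a bare
    diameter in metres.  Strictly decreasing in diameter over the valid range.
    """
    if conditions is None:
        conditions = GasConditions()
    if not isinstance(particle, ParticleSpec):
        particle = ParticleSpec(diameter=float(particle))
    d = particle.diameter
    cc = cunningham_slip_factor(d, conditions)
    mu = conditions.dynamic_viscosity
    value = BOLTZMANN * conditions.temperature * cc / (3.0 * math.pi * mu * d)
    return DiffusionCoefficient(value=value, particle=particle, conditions=conditions)


def sphere_remaining_fraction(
    D: float,
    t: float,
    radius: float,
    *,
    tol: float = 1e-12,
    max_terms: int = 10_000,
) -> float:
    """Fraction of particles still airborne in an absorbing sphere after time t.

    Solution of the diffusion equation in a sphere of radius r with perfectly
    absorbing wall and initially uniform concentration:

        f(t) = (6/pi^2) sum_n n^-2 exp(-n^2 pi^2 D t / r^2)

    Terms are added until the next term falls below ``tol`` (or ``max_terms``
    is hit — the series is provably convergent and this cap is generous even
    for Fourier numbers ~1e-6).  Returns a value in (0, 1], equal to 1 at
    t = 0 and decreasing in both t and D/r^2.
    """
    if D < 0 or t < 0 or radius <= 0:
        raise PhysicsValidationError(
            f"require D >= 0, t >= 0, radius > 0; got D={D}, t={t}, radius={radius}"
        )
    fourier = D * t / radius**2
    if fourier == 0.0:
        return 1.0
    pi2 = math.pi**2
    total = 0.0
    for n in range(1, max_terms + 1):
        term = math.exp(-(n**2) * pi2 * fourier) / n**2
        total += term
        if term < tol:
            break
    return min(1.0, (6.0 / pi2) * total)


# Gormley–Kennedy coefficients for penetration of a fully developed laminar
# tube flow with absorbing wall, parameterized by mu = pi D L / Q.
_GK_SWITCH = 0.02
_GK_SMALL = (2.5638, 1.2, 0.17670)
_GK_LARGE = ((0.81905, 3.6568), (0.09753, 22.305), (0.0325, 56.961), (0.01544, 107.62))


def gormley_kennedy_penetration(mu: float) -> float:
    """Penetration P(mu) of the Graetz problem, mu = pi D L / Q.

    Two-branch classical expansion: an Ingham-type series for mu <= 0.02 and
    a four-term eigenfunction sum above; the branches agree to ~1.5e-4 at the
    switch point.
    """
    if mu < 0:
        raise PhysicsValidationError(f"mu must be >= 0, got {mu}")
    if mu <= _GK_SWITCH:
        a, b, c = _GK_SMALL
        p = 1.0 - a * mu ** (2.0 / 3.0) + b * mu + c * mu ** (4.0 / 3.0)
    else:
        p = sum(g * math.exp(-lam * mu) for g, lam in _GK_LARGE)
    return min(1.0, max(p, 0.0))


def tube_penetration(D: float, length: float, flow: float) -> float:
    """Diffusional penetration of a laminar tube: P(mu), mu = pi D L / Q.

    ``flow`` is the volumetric flow through the tube in m^3/s.  Monotone
    non-increasing in length and D, increasing in flow; -> 1 as mu -> 0.
    """
    if D <= 0 or length <= 0 or flow <= 0:
        raise PhysicsValidationError(
            f"require D, length, flow > 0; got D={D}, length={length}, flow={flow}"
        )
    mu = math.pi * D * length / flow
    return gormley_kennedy_penetration(mu)
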