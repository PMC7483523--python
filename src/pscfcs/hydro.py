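"""Stokes-Einstein conversions and stoichiometry from diffusion times.

For a sphere of hydrodynamic radius R in a solvent of viscosity eta at
temperature T, D = k_B T / (6 pi eta R), and the FCS diffusion time
through a Gaussian focus of waist w_xy is tau = w_xy^2 / (4 D). Assuming
all protein species are spherical with equal density, masses scale as
the cube of the radius and hence of the diffusion time,

    M1 / M2 = (tau1 / tau2)^3,

so a species of unknown mass is weighed against a reference measured in
the same focus. First-order error propagation gives

    var(M1)/M1^2 = 9 (var(tau1)/tau1^2 + var(tau2)/tau2^2).

The chaperone:client stoichiometric ratio follows from the bound and
unbound (apo) client diffusion times,

    r = ((tau_bound/tau_apo)^3 - 1) * M_client / M_chaperone,

and the effective stoichiometric number of a labelled chaperone tracer,
referenced to the free dye, is n = (tau/tau_dye)^3 * M_dye / M_monomer.
Diffusion-limited association rates use the Smoluchowski relation
k+ = 4 pi (D_A + D_B)(R_A + R_B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "BOLTZMANN",
    "AVOGADRO",
    "SolventConditions",
    "FocusGeometry",
    "SpeciesMeasurement",
    "stokes_einstein",
    "mass_from_tau",
    "stoichiometric_ratio",
    "effective_stoichiometry",
    "diffusion_limited_rate",
]

BOLTZMANN = 1.380649e-23  # J/K (exact, SI)
AVOGADRO = 6.02214076e23  # 1/mol (exact, SI)

#: Molecular weight of the free maleimide dye used as diffusion reference
#: (Cy3B maleimide), daltons. Configurable wherever it enters.
DEFAULT_REFERENCE_DYE_MASS = 658.0


@dataclass(frozen=True)
class SolventConditions:
    """Temperature (K) and dynamic viscosity (Pa s). Defaults are water
    at 23 degrees C, the measurement temperature."""

    temperature: float = 296.15
    viscosity: float = 0.9321e-3

    def __post_init__(self):
        if self.temperature <= 0 or self.viscosity <= 0:
            raise InvalidArgumentError("temperature and viscosity must be > 0")


@dataclass(frozen=True)
class FocusGeometry:
    """Lateral waist and axial extent (1/e^2 radii, meters) of the
    Gaussian detection volume."""

    waist: float = 0.25e-6
    axial: float = 1.25e-6

    def __post_init__(self):
        if self.waist <= 0 or self.axial <= 0:
            raise InvalidArgumentError("focus dimensions must be > 0")


@dataclass(frozen=True)
class SpeciesMeasurement:
    """A measured diffusion time with uncertainty and, optionally, a
    known mass (Da) or radius (m)."""

    tau: float
    tau_sd: float = 0.0
    mass: float | None = None
    radius: float | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidArgumentError("tau must be > 0")
        if self.tau_sd < 0:
            raise InvalidArgumentError("tau_sd must be >= 0")
        if self.mass is not None and self.mass <= 0:
            raise InvalidArgumentError("mass must be > 0")
        if self.radius is not None and self.radius <= 0:
            raise InvalidArgumentError("radius must be > 0")


class HydroTriple(NamedTuple):
    diffusion_coefficient: float  # m^2/s
    radius: float  # m
    tau: float | None  # s, None when no focus geometry was supplied


def stokes_einstein(
    conditions: SolventConditions,
    radius: float | None = None,
    diffusion_coefficient: float | None = None,
    tau: float | None = None,
    focus: FocusGeometry | None = None,
) -> HydroTriple:
    """Complete the (D, R, tau) triple from exactly one given quantity.

    ``tau`` requires ``focus``; without a focus the returned tau is None.
    Round-trips are identities to floating-point precision.
    """
    given = [x is not None for x in (radius, diffusion_coefficient, tau)]
    if sum(given) != 1:
        raise InvalidArgumentError("give exactly one of radius, diffusion_coefficient, tau")
    kT = BOLTZMANN * conditions.temperature
    six_pi_eta = 6 * np.pi * conditions.viscosity
    if tau is not None:
        if tau <= 0:
            raise InvalidArgumentError("tau must be > 0")
        if focus is None:
            raise InvalidArgumentError("focus geometry required to convert tau")
        diffusion_coefficient = focus.waist**2 / (4 * tau)
    if diffusion_coefficient is not None:
        if diffusion_coefficient <= 0:
            raise InvalidArgumentError("diffusion coefficient must be > 0")
        radius = kT / (six_pi_eta * diffusion_coefficient)
    else:
        if radius <= 0:
            raise InvalidArgumentError("radius must be > 0")
        diffusion_coefficient = kT / (six_pi_eta * radius)
    out_tau = None
    if focus is not None:
        out_tau = focus.waist**2 / (4 * diffusion_coefficient)
    elif tau is not None:
        out_tau = tau
    return HydroTriple(diffusion_coefficient, radius, out_tau)


def mass_from_tau(
    target: SpeciesMeasurement, reference: SpeciesMeasurement
) -> tuple[float, float]:
    """Mass of ``target`` from the cubic diffusion-time law against a
    reference of known mass; returns (mass, standard deviation) with the
    first-order propagated uncertainty."""
    if reference.mass is None:
        raise InvalidArgumentError("reference species must carry a known mass")
    ratio = target.tau / reference.tau
    mass = reference.mass * ratio**3
    rel_var = 9.0 * (
        (target.tau_sd / target.tau) ** 2 + (reference.tau_sd / reference.tau) ** 2
    )
    return mass, mass * np.sqrt(rel_var)


def stoichiometric_ratio(
    tau_bound: float,
    tau_apo: float,
    m_client: float,
    m_chaperone: float,
    tau_bound_sd: float = 0.0,
    tau_apo_sd: float = 0.0,
) -> tuple[float, float]:
    """Chaperone monomers per client from bound vs apo diffusion times.

    r = ((tau_bound/tau_apo)^3 - 1) * m_client / m_chaperone. The
    uncertainty propagates the tau standard deviations through the cubic
    term to first order. A bound complex should diffuse no faster than
    the apo client; tau_bound < tau_apo yields a negative r and a
    warning-free return (the caller decides how to interpret it).
    """
    if min(tau_bound, tau_apo, m_client, m_chaperone) <= 0:
        raise InvalidArgumentError("all inputs must be > 0")
    q = tau_bound / tau_apo
    mu = m_client / m_chaperone
    r = (q**3 - 1.0) * mu
    # d r / d tau_b = 3 q^3 mu / tau_b ; d r / d tau_a = -3 q^3 mu / tau_a
    var = (3 * q**3 * mu) ** 2 * (
        (tau_bound_sd / tau_bound) ** 2 + (tau_apo_sd / tau_apo) ** 2
    )
    return r, float(np.sqrt(var))


def effective_stoichiometry(
    tau_d: float,
    tau_ref: float,
    m_ref: float = DEFAULT_REFERENCE_DYE_MASS,
    m_monomer: float = 18800.0,
) -> float:
    """Effective number of chaperone monomers per diffusing particle,
    n = (tau_d/tau_ref)^3 * m_ref/m_monomer, the observable of the
    self-trimerization titration (n runs from 1 for free monomer to 3
    for the trimer)."""
    if min(tau_d, tau_ref, m_ref, m_monomer) <= 0:
        raise InvalidArgumentError("all inputs must be > 0")
    return (tau_d / tau_ref) ** 3 * (m_ref / m_monomer)


def diffusion_limited_rate(
    species_a: tuple[float, float], species_b: tuple[float, float]
) -> float:
    """Smoluchowski diffusion-limited association rate constant.

    ``species_a`` and ``species_b`` are (D in m^2/s, R in m) pairs.
    Returns k+ = 4 pi (D_A + D_B)(R_A + R_B) in M^-1 s^-1 (converted via
    Avogadro's number and m^3 -> L).
    """
    d_a, r_a = species_a
    d_b, r_b = species_b
    if min(d_a, r_a, d_b, r_b) <= 0:
        raise InvalidArgumentError("diffusion coefficients and radii must be > 0")
    k_si = 4 * np.pi * (d_a + d_b) * (r_a + r_b)  # m^3 / s per molecule pair
    return k_si * AVOGADRO * 1e3
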