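"""Mass-action models for chaperone self-trimerization and client
binding, and least-squares fitting of titration data.

Three coupled equilibria describe the Skp-OmpC system:

* self-trimerization, 3 S <-> S3, with dissociation constant
  K = [S]^3 / [S3] (nM^2). The total monomer concentration at which half
  the monomers sit in trimers is C_1/2 = sqrt(4K/3).
* cooperative client binding at sub-nanomolar chaperone, summarized by a
  Hill isotherm p = c^n / (K_D^n + c^n) in the total chaperone
  concentration c.
* binding of a second trimer at micromolar chaperone,
  client.S3 + S3 <-> client.(S3)2 with dissociation constant K_D',
  where the free-trimer concentration follows from the trimerization
  equilibrium at the given total.

The trimerization titration observable is the effective stoichiometric
number of a labelled tracer monomer, n(total) = 1 + 2 f(total), with f
the fraction of monomers incorporated in trimers; the tracer is treated
as chemically identical to the unlabelled monomer.

Free energies are referenced to the 1 M standard state,
dG = R T ln(K_D / 1 M).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import lmfit
from scipy.optimize import brentq

from .exceptions import (
    DegenerateInputError,
    FitFailureError,
    InvalidArgumentError,
    UnboundedEstimateError,
)
from .hydro import SolventConditions

__all__ = [
    "TrimerEquilibrium",
    "HillBinding",
    "SecondTrimerBinding",
    "trimer_species",
    "trimer_c_half",
    "fit_trimer_titration",
    "hill_fraction",
    "fit_hill",
    "second_trimer_fraction",
    "fit_second_trimer",
    "binding_free_energy",
    "apparent_rates",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)


@dataclass(frozen=True)
class TrimerEquilibrium:
    """3 S <-> S3 with K = [S]^3/[S3] in nM^2."""

    K: float

    def __post_init__(self):
        if self.K <= 0:
            raise InvalidArgumentError("trimerization K must be > 0")


@dataclass(frozen=True)
class HillBinding:
    """Hill isotherm: apparent dissociation constant (pM) and Hill
    coefficient."""

    k_d: float
    n_hill: float

    def __post_init__(self):
        if self.k_d <= 0 or self.n_hill <= 0:
            raise InvalidArgumentError("k_d and n_hill must be > 0")


@dataclass(frozen=True)
class SecondTrimerBinding:
    """Second-trimer binding step with K_D' (uM) coupled to the
    trimerization equilibrium that sets the free trimer concentration."""

    k_d_prime: float
    trimer: TrimerEquilibrium

    def __post_init__(self):
        if self.k_d_prime <= 0:
            raise InvalidArgumentError("k_d_prime must be > 0")


def trimer_species(model: TrimerEquilibrium, total: float) -> tuple[float, float, float]:
    """Equilibrium concentrations at a given total monomer concentration.

    Solves the conservation law [S] + 3 [S]^3 / K = total for the unique
    non-negative monomer concentration (the left side is strictly
    increasing), then [S3] = [S]^3 / K. Returns ([S], [S3],
    trimer_fraction f = 3[S3]/total), all in nM; f = 0 at total = 0 by
    convention. Conservation holds to 1e-10 relative.
    """
    if total < 0:
        raise InvalidArgumentError("total concentration must be >= 0")
    if total == 0:
        return 0.0, 0.0, 0.0

    def balance(s):
        return s + 3 * s**3 / model.K - total

    s = brentq(balance, 0.0, total, xtol=1e-300, rtol=1e-15)
    s3 = s**3 / model.K
    f = 3 * s3 / total
    return float(s), float(s3), float(f)


def trimer_c_half(model: TrimerEquilibrium) -> float:
    """Total concentration at which half the monomers are trimerized.

    At f = 1/2 the conservation law gives C_1/2 = sqrt(4K/3) in closed
    form (nM for K in nM^2).
    """
    return float(np.sqrt(4.0 * model.K / 3.0))


def _trimer_fraction_curve(K: float, totals: np.ndarray) -> np.ndarray:
    model = TrimerEquilibrium(K)
    return np.array([trimer_species(model, t)[2] for t in totals])


def fit_trimer_titration(
    points: Iterable[tuple[float, float]],
    k_init: float | None = None,
) -> tuple[TrimerEquilibrium, float]:
    """Fit the trimerization constant K to an effective-stoichiometry
    titration.

    ``points`` are (total nM, observed n) pairs with the model
    n(total) = 1 + 2 f(total). Returns (fitted model, standard error of
    K). Data that carry no trimerization signal (n flat at the monomer
    value) leave K unbounded and raise :class:`UnboundedEstimateError`.
    """
    pts = list(points)
    if len(pts) < 4:
        raise InvalidArgumentError("need >= 4 titration points")
    totals = np.array([p[0] for p in pts], dtype=float)
    ns = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(ns) < 1e-12:
        raise UnboundedEstimateError("flat titration: K is not identifiable")
    if k_init is None:
        k_init = float(np.median(totals)) ** 2
    params = lmfit.Parameters()
    # fit log10 K for scale invariance across many decades
    params.add("logk", value=np.log10(k_init), min=-6, max=18)

    def residual(p):
        K = 10.0 ** p["logk"].value
        return 1.0 + 2.0 * _trimer_fraction_curve(K, totals) - ns

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailureError(
            f"trimer titration fit failed: {result.message}",
            best_values=dict(result.params.valuesdict()),
        )
    logk = result.params["logk"]
    if logk.value >= 17.5 or logk.value <= -5.5:
        raise UnboundedEstimateError(
            f"K estimate ran to the bound (log10 K = {logk.value:.2f}): data do not "
            "constrain the trimerization"
        )
    K = 10.0**logk.value
    # delta-method standard error on K from the log-space stderr
    k_stderr = float(K * np.log(10) * logk.stderr) if logk.stderr else float("nan")
    return TrimerEquilibrium(K), k_stderr


def hill_fraction(model: HillBinding, total_chaperone) -> np.ndarray | float:
    """Bound fraction p = c^n / (K_D^n + c^n); p(K_D) = 1/2 exactly."""
    c = np.asarray(total_chaperone, dtype=float)
    if np.any(c < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / model.k_d) ** model.n_hill, 0.0)
    p = ratio / (1.0 + ratio)
    return float(p) if np.isscalar(total_chaperone) else p


def fit_hill(
    points: Iterable[tuple[float, float]],
    n_fixed: float | None = None,
    free_scale: bool = False,
) -> tuple[HillBinding, dict]:
    """Fit (K_D, n_Hill) to normalized bound-fraction data.

    ``points`` are (total chaperone, bound fraction) pairs in consistent
    concentration units (K_D is returned in the same units). ``n_fixed``
    pins the Hill coefficient (n_fixed=1 reduces to a Langmuir fit);
    ``free_scale`` adds a multiplicative amplitude for un-normalized
    inputs. Returns the fitted model and a dict of standard errors.
    """
    pts = list(points)
    if len(pts) < 4:
        raise InvalidArgumentError("need >= 4 binding points")
    c = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(y) < 1e-12:
        raise UnboundedEstimateError("flat binding curve: K_D is not identifiable")
    params = lmfit.Parameters()
    params.add("logk", value=np.log10(np.median(c)), min=np.log10(c.min()) - 6,
               max=np.log10(c.max()) + 6)
    params.add("n", value=1.0 if n_fixed is None else n_fixed, min=0.05, max=10,
               vary=n_fixed is None)
    params.add("scale", value=1.0, min=0, vary=free_scale)

    def residual(p):
        model = HillBinding(10.0 ** p["logk"].value, p["n"].value)
        return p["scale"].value * hill_fraction(model, c) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailureError(
            f"Hill fit failed: {result.message}",
            best_values=dict(result.params.valuesdict()),
        )
    logk = result.params["logk"]
    k_d = 10.0**logk.value
    stderr = {
        "k_d": float(k_d * np.log(10) * logk.stderr) if logk.stderr else float("nan"),
        "n_hill": float(result.params["n"].stderr or "nan"),
    }
    return HillBinding(k_d, result.params["n"].value), stderr


def second_trimer_fraction(model: SecondTrimerBinding, total_chaperone) -> np.ndarray | float:
    """Fraction of client carrying a second trimer,
    f = [S3] / (K_D' + [S3]), with the free trimer concentration [S3]
    from the trimerization equilibrium at the given total.

    ``total_chaperone`` and ``k_d_prime`` are in uM; the embedded
    trimerization constant is in nM^2.
    """
    totals = np.atleast_1d(np.asarray(total_chaperone, dtype=float))
    if np.any(totals < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    s3_nm = np.array([trimer_species(model.trimer, t * 1e3)[1] for t in totals])
    s3_um = s3_nm * 1e-3
    f = s3_um / (model.k_d_prime + s3_um)
    return float(f[0]) if np.isscalar(total_chaperone) else f


def fit_second_trimer(
    points: Iterable[tuple[float, float]],
    trimer: TrimerEquilibrium,
) -> tuple[SecondTrimerBinding, float]:
    """Fit K_D' (uM) to a normalized second-trimer-fraction titration;
    the trimerization constant is supplied, not co-fitted. Returns
    (fitted model, standard error of K_D')."""
    pts = list(points)
    if len(pts) < 4:
        raise InvalidArgumentError("need >= 4 titration points")
    totals = np.array([p[0] for p in pts], dtype=float)
    f_obs = np.array([p[1] for p in pts], dtype=float)
    if np.all(np.abs(f_obs) < 1e-12):
        raise UnboundedEstimateError("all-zero fractions: K_D' is not identifiable")
    s3_um = np.array([trimer_species(trimer, t * 1e3)[1] for t in totals]) * 1e-3
    params = lmfit.Parameters()
    params.add("logk", value=np.log10(np.median(s3_um[s3_um > 0])), min=-8, max=8)

    def residual(p):
        kdp = 10.0 ** p["logk"].value
        return s3_um / (kdp + s3_um) - f_obs

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailureError(
            f"second-trimer fit failed: {result.message}",
            best_values=dict(result.params.valuesdict()),
        )
    logk = result.params["logk"]
    if logk.value >= 7.5:
        raise UnboundedEstimateError("K_D' estimate ran to the upper bound")
    kdp = 10.0**logk.value
    stderr = float(kdp * np.log(10) * logk.stderr) if logk.stderr else float("nan")
    return SecondTrimerBinding(kdp, trimer), stderr


def binding_free_energy(
    dissociation_constant: float,
    conditions: SolventConditions = SolventConditions(),
) -> float:
    """Standard binding free energy dG = R T ln(K_D / 1 M) in kcal/mol.

    ``dissociation_constant`` in molar; negative dG for K_D < 1 M.
    """
    if dissociation_constant <= 0:
        raise InvalidArgumentError("dissociation constant must be > 0")
    return GAS_CONSTANT_KCAL * conditions.temperature * float(np.log(dissociation_constant))


def apparent_rates(
    trimer: TrimerEquilibrium,
    k_plus_monomer: float,
    k_plus_trimer: float,
    total: float,
) -> tuple[float, float]:
    """Pseudo-first-order association rates of the monomer and trimer
    pathways at a given total monomer concentration (nM).

    Returns (k+_mono [S], k+_tri [S3]) in the rate constants' units
    times nM. Because [S3] grows as [S]^3, the trimer pathway overtakes
    the monomer pathway as the total rises.
    """
    if k_plus_monomer <= 0 or k_plus_trimer <= 0:
        raise InvalidArgumentError("rate constants must be > 0")
    s, s3, _ = trimer_species(trimer, total)
    return k_plus_monomer * s, k_plus_trimer * s3
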