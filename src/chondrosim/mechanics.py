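"""Aggrecan osmotic pressure and equilibrium consolidation mechanics.

Articular cartilage resists compression through the Donnan osmotic
pressure of its fixed-charge aggrecan matrix.  The swelling pressure of
aggrecan at mass density ``a`` (mg/mL) is modelled by a cubic virial
expansion

    Pi(a) = R*T*(alpha1*a + alpha2*a**2 + alpha3*a**3)

with the virial coefficients measured for extracted aggrecan.  Under a
sustained compressive stress ``sigma`` the tissue consolidates: fluid is
expressed until the locally concentrated aggrecan (density ``a/(1-eps)``
at strain ``eps``) pushes back with pressure equal to the applied
stress.  Solving ``Pi(a/(1-eps)) = sigma`` for ``eps`` gives the
equilibrium consolidation strain, and the tissue-health metric is the
margin between a tolerable strain threshold and the strain the tissue
actually reaches under a standard test load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from scipy.optimize import brentq

__all__ = [
    "OsmoticParameters",
    "HealthSpec",
    "UnresistedLoadError",
    "osmotic_pressure",
    "equilibrium_strain",
    "tissue_health",
]

logger = logging.getLogger(__name__)

#: Absolute tolerance on the consolidated density root (mg/mL).  The
#: induced strain error is well below 1e-9 for physiologic densities.
DENSITY_XTOL = 1e-10


class UnresistedLoadError(ValueError):
    """A positive stress was applied to tissue with no aggrecan.

    With zero aggrecan there is no osmotic pressure at any strain, so no
    finite equilibrium exists: the balance ``Pi(a/(1-eps)) = sigma`` has
    no solution for ``eps`` in [0, 1).
    """


@dataclass(frozen=True)
class OsmoticParameters:
    """Constants of the aggrecan osmotic-pressure virial expansion.

    Attributes
    ----------
    gas_constant : float
        Gas constant R in mL·kPa·mol⁻¹·K⁻¹.
    temperature : float
        Absolute temperature in K.
    virial1, virial2, virial3 : float
        Virial coefficients alpha1 (mol/mg), alpha2 (mol·mL/mg²) and
        alpha3 (mol·mL²/mg³) of the expansion.
    """

    gas_constant: float = 8.3e3
    temperature: float = 300.0
    virial1: float = 1.4e-7
    virial2: float = 4.4e-9
    virial3: float = 5.7e-11

    def __post_init__(self) -> None:
        for name in ("gas_constant", "temperature", "virial1", "virial2", "virial3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"OsmoticParameters.{name} must be strictly positive")

    @property
    def rt(self) -> float:
        """R*T prefactor in mL·kPa/mg units once multiplied by the virials."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class HealthSpec:
    """Definition of the consolidated-strain tissue-health metric.

    Health is ``strain_threshold`` minus the equilibrium strain under
    ``test_stress``; a negative value means the tissue consolidates past
    the tolerable strain and is in the osteoarthritis danger regime.
    """

    test_stress: float = 400.0  # kPa
    strain_threshold: float = 0.35  # strain fraction

    def __post_init__(self) -> None:
        if not self.test_stress > 0:
            raise ValueError("HealthSpec.test_stress must be strictly positive")
        if not 0.0 < self.strain_threshold < 1.0:
            raise ValueError("HealthSpec.strain_threshold must lie in (0, 1)")


def osmotic_pressure(aggrecan_density: float, params: OsmoticParameters | None = None) -> float:
    """Osmotic pressure (kPa) of aggrecan at the given density (mg/mL).

    Strictly increasing and convex in density, zero at zero density.
    """
    if params is None:
        params = OsmoticParameters()
    a = float(aggrecan_density)
    if a < 0:
        raise ValueError(f"aggrecan density must be non-negative, got {a}")
    return params.rt * (params.virial1 * a + params.virial2 * a * a + params.virial3 * a * a * a)


@lru_cache(maxsize=4096)
def _density_at_pressure(sigma: float, params: OsmoticParameters) -> float:
    """Invert the virial expansion: density x with Pi(x) = sigma.

    Pi is strictly increasing on x >= 0 with Pi(0) = 0, so the root is
    unique.  Bracketed root-finding is used rather than the cubic closed
    form so the solver survives future generalisations of Pi.  Cached
    because the health metric repeatedly inverts the same test stress.
    """
    if sigma <= 0:
        return 0.0
    hi = 100.0
    while osmotic_pressure(hi, params) < sigma:
        hi *= 2.0
    return brentq(
        lambda x: osmotic_pressure(x, params) - sigma, 0.0, hi,
        xtol=DENSITY_XTOL, rtol=8.9e-16,
    )


def equilibrium_strain(
    aggrecan_density: float,
    applied_stress: float,
    params: OsmoticParameters | None = None,
) -> float:
    """Equilibrium consolidation strain under a sustained stress.

    Solves ``Pi(a/(1-eps)) = sigma`` for the unique ``eps`` in [0, 1).
    Writing ``x = a/(1-eps)`` for the compressed density, the balance is
    ``x = Pi^{-1}(sigma)``, i.e. ``eps = 1 - a/Pi^{-1}(sigma)``, which a
    single bracketed root-find on the monotone virial polynomial
    delivers to solver tolerance.

    When the applied stress does not exceed the resting osmotic pressure
    ``Pi(a)`` the tissue does not consolidate and the strain is clamped
    to 0 (swelling is outside the model's scope).

    Raises
    ------
    UnresistedLoadError
        If ``aggrecan_density`` is 0 while ``applied_stress`` > 0.
    ValueError
        For negative density or stress.
    """
    if params is None:
        params = OsmoticParameters()
    a = float(aggrecan_density)
    sigma = float(applied_stress)
    if a < 0:
        raise ValueError(f"aggrecan density must be non-negative, got {a}")
    if sigma < 0:
        raise ValueError(f"applied stress must be non-negative, got {sigma}")
    if sigma == 0.0:
        return 0.0
    if a == 0.0:
        raise UnresistedLoadError(
            "positive stress applied to tissue with zero aggrecan density: "
            "no finite consolidation equilibrium exists"
        )
    if sigma <= osmotic_pressure(a, params):
        logger.debug(
            "stress %.6g kPa below resting osmotic pressure at a=%.6g mg/mL; "
            "strain clamped to 0", sigma, a,
        )
        return 0.0
    x = _density_at_pressure(sigma, params)
    return 1.0 - a / x


def tissue_health(
    aggrecan_density: float,
    spec: HealthSpec | None = None,
    params: OsmoticParameters | None = None,
) -> float:
    """Tissue health: threshold strain minus strain under the test load.

    With the defaults, ``0.35 - eps(a, 400 kPa)``.  Negative health
    means the cartilage consolidates beyond the tolerable strain under
    the standard test load — the osteoarthritis danger regime.  Strictly
    increasing in aggrecan density.
    """
    if spec is None:
        spec = HealthSpec()
    return spec.strain_threshold - equilibrium_strain(
        aggrecan_density, spec.test_stress, params
    )
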