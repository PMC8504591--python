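"""Depth-resolved fluorescence-signal model and foil-thickness optimization.

A foil of thickness ``t`` is irradiated from above at normal incidence.
Primary photons of energy E are attenuated with the foil's total coefficient
``mu_p(E)``; K-shell photoelectric absorptions (linear coefficient
``mu_K(E)``) produce K-alpha photons with probability ``omega_Ka`` (the total
radiative K-alpha yield), which escape downward through the remaining foil
with the foil's total coefficient at the K-alpha energy, ``mu_f``, and then
through the listed path materials toward the in-camera scoring region.

Integrating the generation depth analytically gives the per-energy signal

    mu_K(E) / (mu_p(E) - mu_f) * (exp(-mu_f t) - exp(-mu_p(E) t))

with the limit ``mu_K t exp(-mu t)`` when ``mu_p = mu_f``.  The spectrum-
weighted signal is the sum over energy bins of the fluence weight times
``omega_Ka * E_Ka`` times the depth integral times the path transmission.
The quantity is relative (detector response and solid angle are constant
factors) and is degree-1 homogeneous in the spectrum weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attenuation import get_table, k_shell_mu, mu_linear
from .constants import FLUORESCENCE_ELEMENTS, ElementConstants
from .errors import ConfigurationError, ElementLookupError
from .materials import AIR, POLYCARBONATE, MaterialComposition


@dataclass(frozen=True)
class FoilSpec:
    """A fluorescence foil: element, thickness and optional density override."""

    element: str
    thickness_um: float
    density: float | None = None  # g/cm^3 override

    def __post_init__(self) -> None:
        if self.element not in FLUORESCENCE_ELEMENTS:
            raise ElementLookupError(
                f"{self.element!r} is not a supported fluorescence foil element "
                f"(have {sorted(FLUORESCENCE_ELEMENTS)})"
            )
        if self.thickness_um <= 0:
            raise ValueError("foil thickness must be positive")

    @property
    def constants(self) -> ElementConstants:
        return FLUORESCENCE_ELEMENTS[self.element]

    @property
    def rho(self) -> float:
        return self.density if self.density is not None else self.constants.density


#: Default escape path for the mammography setup: the 2.5 mm polycarbonate
#: breast support plus the air column between the foil plane (63.5 mm) and
#: the detector.  The open slit means no brass lies in the escape path.
DEFAULT_ESCAPE_PATH: tuple[tuple[MaterialComposition, float], ...] = (
    (POLYCARBONATE, 2500.0),
    (AIR, 61000.0),
)


def path_transmission(
    energy_kev: float,
    path_materials: tuple[tuple[MaterialComposition, float], ...],
) -> float:
    """Transmission of a photon through (material, thickness_um) layers."""
    total = 0.0
    for material, t_um in path_materials:
        total += mu_linear(material, energy_kev, "total") * t_um * 1e-4
    return float(np.exp(-total))


def fluorescence_signal(
    foil: FoilSpec,
    spectrum,
    path_materials: tuple[tuple[MaterialComposition, float], ...] = DEFAULT_ESCAPE_PATH,
) -> float:
    """Relative K-alpha signal reaching the in-camera scoring region.

    Returns 0 when the spectrum has no support above the foil K-edge.
    """
    const = foil.constants
    rho = foil.rho
    t_cm = foil.thickness_um * 1e-4
    e_ka = const.k_alpha_kev
    table = get_table(foil.element)

    energies = np.asarray(spectrum.energies, dtype=float)
    weights = np.asarray(spectrum.weights, dtype=float)
    above = (energies >= const.k_edge_kev) & (weights > 0)
    if not np.any(above):
        return 0.0
    e = energies[above]
    w = weights[above]

    mu_p = rho * table.mu_over_rho(e, "total")  # primary, 1/cm
    mu_f = rho * table.mu_over_rho(e_ka, "total")  # fluorescence escape, 1/cm
    mu_k = k_shell_mu(foil.element, e, density=rho)  # K-shell PE, 1/cm

    # (exp(-mu_f t) - exp(-mu_p t)) / (mu_p - mu_f) rewritten with expm1 to
    # stay cancellation-free as mu_p -> mu_f, where it tends to t exp(-mu t)
    diff = mu_p - mu_f
    exact = diff == 0.0
    ratio = np.where(
        exact,
        t_cm * np.exp(-mu_f * t_cm),
        np.exp(-mu_f * t_cm) * -np.expm1(-np.where(exact, 1.0, diff) * t_cm)
        / np.where(exact, 1.0, diff),
    )
    depth = mu_k * ratio
    t_path = path_transmission(e_ka, path_materials)
    return float(np.sum(w * const.k_yield * e_ka * depth) * t_path)


def monoenergetic_optimal_thickness_um(mu_p: float, mu_f: float) -> float:
    """Analytic argmax of the depth integral for a monoenergetic beam, in um.

    ``t* = ln(mu_p / mu_f) / (mu_p - mu_f)`` (coefficients in 1/cm), with the
    limit ``1/mu`` when the two coefficients coincide.
    """
    if mu_p <= 0 or mu_f <= 0:
        raise ValueError("attenuation coefficients must be positive")
    if abs(mu_p - mu_f) < 1e-12 * mu_p:
        return 1e4 / mu_p
    return 1e4 * np.log(mu_p / mu_f) / (mu_p - mu_f)


@dataclass(frozen=True)
class ThicknessScan:
    """Signal curve over a thickness grid for one foil element."""

    element: str
    thicknesses_um: np.ndarray  # ascending
    signals: np.ndarray  # raw relative signal
    best_um: float

    @property
    def normalized(self) -> np.ndarray:
        """Curve normalized to its own maximum (unit peak)."""
        return self.signals / self.signals.max()


def optimize_thickness(
    element: str,
    spectrum,
    grid_um,
    path_materials: tuple[tuple[MaterialComposition, float], ...] = DEFAULT_ESCAPE_PATH,
) -> ThicknessScan:
    """Scan foil thicknesses and pick the signal-maximizing one.

    Ties are broken toward the thinner foil.  Raises on an empty grid.
    """
    grid = np.asarray(sorted(grid_um), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("thickness grid must not be empty")
    if np.any(grid <= 0):
        raise ConfigurationError("thicknesses must be positive")
    signals = np.array(
        [
            fluorescence_signal(FoilSpec(element, t), spectrum, path_materials)
            for t in grid
        ]
    )
    # near-ties (within 1e-9 relative) resolve toward the thinner foil
    peak = signals.max()
    best = float(grid[signals >= peak * (1.0 - 1e-9)][0])
    return ThicknessScan(element, grid, signals, best)
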