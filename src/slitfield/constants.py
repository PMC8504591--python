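"""Atomic and fluorescence constants.

The K-shell relaxation data (edge and K-alpha energies, radiative yield) for
the candidate foil elements follow the NIST reference values for Cu, Zr, Mo,
Ag and Sn.  The yield is the *total* radiative yield of the K-alpha emission,
i.e. the fluorescence yield combined with the K-alpha branching fraction, so
it can be used directly as the photons-per-K-vacancy factor in the signal
model.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA-style physical constants used across the physics modules
AVOGADRO = 6.02214076e23  # 1/mol
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13  # cm
HC_KEV_ANGSTROM = 12.398419843  # keV * Angstrom
ELECTRON_REST_KEV = 510.99895  # keV
THOMSON_CROSS_SECTION_CM2 = 0.66524587e-24  # cm^2


@dataclass(frozen=True)
class ElementConstants:
    """K-shell fluorescence properties of a candidate foil element.

    Energies are stored in eV; ``k_yield`` is the total radiative K-alpha
    yield per K vacancy, a fraction in (0, 1].
    """

    symbol: str
    Z: int
    density: float  # g/cm^3
    k_edge: float  # eV
    k_alpha: float  # eV
    k_yield: float  # fraction

    def __post_init__(self) -> None:
        if not self.k_alpha < self.k_edge:
            raise ValueError(f"{self.symbol}: K-alpha must lie below the K-edge")
        if not 0.0 < self.k_yield <= 1.0:
            raise ValueError(f"{self.symbol}: yield must be in (0, 1]")
        if not self.density > 0:
            raise ValueError(f"{self.symbol}: density must be positive")

    @property
    def k_edge_kev(self) -> float:
        return self.k_edge / 1000.0

    @property
    def k_alpha_kev(self) -> float:
        return self.k_alpha / 1000.0


#: Fluorescence properties of the candidate foil elements.
FLUORESCENCE_ELEMENTS: dict[str, ElementConstants] = {
    e.symbol: e
    for e in (
        ElementConstants("Cu", 29, 8.96, 8981.0, 8048.0, 0.454),
        ElementConstants("Zr", 40, 6.51, 17996.0, 15775.0, 0.734),
        ElementConstants("Mo", 42, 10.22, 20000.0, 17479.0, 0.767),
        ElementConstants("Ag", 47, 10.50, 25516.0, 22163.0, 0.831),
        ElementConstants("Sn", 50, 7.31, 29200.0, 25271.0, 0.860),
    )
}

#: Elements covered by the packaged attenuation tables.
ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Al": 13, "Ar": 18,
    "Cu": 29, "Zn": 30, "Zr": 40, "Mo": 42, "Ag": 47, "Sn": 50, "Pb": 82,
}

ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Al": 26.982,
    "Ar": 39.948, "Cu": 63.546, "Zn": 65.38, "Zr": 91.224, "Mo": 95.95,
    "Ag": 107.868, "Sn": 118.710, "Pb": 207.2,
}

#: Bulk densities of the solid elements (g/cm^3), used for pure-element
#: materials and filters.  Foil candidates use the NIST reference densities.
ELEMENT_DENSITY: dict[str, float] = {
    "Al": 2.699, "Cu": 8.96, "Zn": 7.134, "Zr": 6.51, "Mo": 10.22,
    "Ag": 10.50, "Sn": 7.31, "Pb": 11.35,
}

#: Absorption-edge energies (keV) above 1 keV, used to place duplicated grid
#: points in the attenuation tables so interpolation never bridges an edge.
ABSORPTION_EDGES_KEV: dict[str, tuple[float, ...]] = {
    "Al": (1.560,),
    "Ar": (3.206,),
    "Cu": (8.981, 1.096),
    "Zn": (9.659, 1.194, 1.044, 1.020),
    "Zr": (17.996, 2.532, 2.307, 2.223),
    "Mo": (20.000, 2.866, 2.625, 2.520),
    "Ag": (25.516, 3.806, 3.524, 3.351),
    "Sn": (29.200, 4.465, 4.156, 3.929),
    "Pb": (88.005, 15.861, 15.200, 13.035, 3.851, 3.554, 3.066, 2.586, 2.484),
}

#: K-edge energies (keV) of table elements that have one inside 1-150 keV.
K_EDGE_KEV: dict[str, float] = {
    "Al": 1.560, "Ar": 3.206, "Cu": 8.981, "Zn": 9.659, "Zr": 17.996,
    "Mo": 20.000, "Ag": 25.516, "Sn": 29.200, "Pb": 88.005,
}
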