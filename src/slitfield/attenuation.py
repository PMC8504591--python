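"""Mass-attenuation tables, mixture rule, mean free paths, K-shell partition.

The packaged tables (``data/attenuation.csv``) hold total and photoelectric
mass attenuation coefficients per element on a 1-150 keV grid with duplicated
points just below and above every absorption edge.  Interpolation is linear in
log-log space; because the duplicated edge points pin the segments on either
side, interpolation never bridges an edge discontinuity.

The K-shell share of the photoelectric coefficient is obtained with the
jump-ratio approximation: above the K-edge a fraction ``1 - 1/J_K`` of
photoelectric interactions occur in the K shell, where ``J_K`` is the ratio of
the photoelectric coefficients just above and just below the edge.  This is
accurate to a few percent above the edge, which is sufficient for ranking foil
thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .constants import ELEMENT_DENSITY, K_EDGE_KEV
from .errors import ElementLookupError, EnergyRangeError
from .materials import MaterialComposition

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 150.0

_CHANNELS = ("total", "photoelectric")


@dataclass(frozen=True)
class AttenuationTable:
    """Per-element grid of mass attenuation coefficients (cm^2/g)."""

    element: str
    energy_kev: np.ndarray  # ascending, with duplicated edge points
    mu_rho_total: np.ndarray
    mu_rho_photo: np.ndarray

    def mu_over_rho(self, energy_kev, channel: str = "total"):
        """Interpolate mu/rho (cm^2/g) at ``energy_kev`` (scalar or array)."""
        if channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise EnergyRangeError(
                f"energy outside tabulated range "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV"
            )
        values = self.mu_rho_total if channel == "total" else self.mu_rho_photo
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_kev), np.log(values))
        )
        return float(out) if np.isscalar(energy_kev) else out

    def k_edge_jump_ratio(self) -> float:
        """Photoelectric jump ratio across the K-edge (1 if no edge in range)."""
        edge = K_EDGE_KEV.get(self.element)
        if edge is None:
            return 1.0
        below = self.mu_rho_photo[self.energy_kev < edge][-1]
        above = self.mu_rho_photo[self.energy_kev > edge][0]
        return float(above / below)


@lru_cache(maxsize=1)
def _load_tables() -> dict[str, AttenuationTable]:
    text = (
        resources.files("slitfield").joinpath("data/attenuation.csv").read_text()
    )
    rows: dict[str, list[tuple[float, float, float]]] = {}
    for line in text.splitlines()[1:]:
        sym, e, tot, pe = line.split(",")
        rows.setdefault(sym, []).append((float(e), float(tot), float(pe)))
    tables = {}
    for sym, data in rows.items():
        arr = np.array(data)
        tables[sym] = AttenuationTable(sym, arr[:, 0], arr[:, 1], arr[:, 2])
    return tables


def get_table(element: str) -> AttenuationTable:
    tables = _load_tables()
    try:
        return tables[element]
    except KeyError:
        raise ElementLookupError(
            f"element {element!r} not in packaged attenuation tables"
        ) from None


def mu_over_rho(element: str, energy_kev, channel: str = "total"):
    """Elemental mass attenuation coefficient, cm^2/g."""
    return get_table(element).mu_over_rho(energy_kev, channel)


def mu_linear(
    material: MaterialComposition, energy_kev, channel: str = "total"
):
    """Linear attenuation coefficient of a material, 1/cm.

    Mass-weighted mixture rule over the constituents times the bulk density.
    Continuous in energy except at constituent absorption edges.
    """
    e = np.asarray(energy_kev, dtype=float)
    mix = np.zeros_like(e)
    for sym, w in material.constituents:
        mix = mix + w * get_table(sym).mu_over_rho(e, channel)
    out = material.density * mix
    return float(out) if np.isscalar(energy_kev) else out


def mean_free_path(
    material: MaterialComposition, energy_kev, channel: str = "total"
):
    """Mean free path in micrometres for the given interaction channel."""
    mu = mu_linear(material, energy_kev, channel)
    return 1e4 / mu


def k_shell_mu(element: str, energy_kev, density: float | None = None):
    """K-shell photoelectric linear attenuation of a pure element, 1/cm.

    Returns ``mu_pe(E) * (1 - 1/J_K)`` above the K-edge and 0 below it, where
    ``J_K`` is the jump ratio read off the table discontinuity.
    """
    table = get_table(element)
    edge = K_EDGE_KEV.get(element)
    if edge is None:
        e = np.asarray(energy_kev, dtype=float)
        return 0.0 if np.isscalar(energy_kev) else np.zeros_like(e)
    if density is None:
        density = ELEMENT_DENSITY[element]
    jump = table.k_edge_jump_ratio()
    k_fraction = 1.0 - 1.0 / jump
    e = np.asarray(energy_kev, dtype=float)
    mu_pe = density * table.mu_over_rho(np.maximum(e, edge), "photoelectric")
    out = np.where(e >= edge, k_fraction * mu_pe, 0.0)
    return float(out) if np.isscalar(energy_kev) else out
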