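"""Material compositions (mixture rule inputs) and common presets."""

from __future__ import annotations

from dataclasses import dataclass

from .constants import ATOMIC_NUMBER, ELEMENT_DENSITY
from .errors import ElementLookupError


@dataclass(frozen=True)
class MaterialComposition:
    """A homogeneous material given as elemental mass fractions.

    ``constituents`` maps element symbols to mass fractions that must sum to
    one; ``density`` is the bulk density in g/cm^3.
    """

    name: str
    constituents: tuple[tuple[str, float], ...]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(w for _, w in self.constituents)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total!r}, expected 1"
            )
        for sym, w in self.constituents:
            if sym not in ATOMIC_NUMBER:
                raise ElementLookupError(f"unknown element {sym!r} in {self.name}")
            if w < 0:
                raise ValueError(f"{self.name}: negative mass fraction for {sym}")


def element_material(symbol: str, density: float | None = None) -> MaterialComposition:
    """A pure-element material at its bulk density (or an override)."""
    if symbol not in ATOMIC_NUMBER:
        raise ElementLookupError(f"unknown element {symbol!r}")
    if density is None:
        try:
            density = ELEMENT_DENSITY[symbol]
        except KeyError:
            raise ElementLookupError(
                f"no default density for {symbol!r}; pass one explicitly"
            ) from None
    return MaterialComposition(symbol, ((symbol, 1.0),), density)


#: Brass alloy 360 used for the camera plates.
BRASS = MaterialComposition(
    "brass-360", (("Cu", 0.615), ("Zn", 0.355), ("Pb", 0.030)), 8.5
)

#: Polycarbonate (C16H14O3) breast-support plate.
POLYCARBONATE = MaterialComposition(
    "polycarbonate", (("H", 0.055491), ("C", 0.755746), ("O", 0.188763)), 1.20
)

#: Dry air near sea level.
AIR = MaterialComposition(
    "air", (("C", 0.000124), ("N", 0.755268), ("O", 0.231781), ("Ar", 0.012827)),
    1.205e-3,
)

ALUMINUM = element_material("Al")
SILVER = element_material("Ag")

_PRESETS = {
    "brass": BRASS,
    "polycarbonate": POLYCARBONATE,
    "air": AIR,
    "aluminum": ALUMINUM,
    "silver": SILVER,
}


def resolve_material(spec: str | MaterialComposition) -> MaterialComposition:
    """Resolve a material given as a preset name, element symbol or object."""
    if isinstance(spec, MaterialComposition):
        return spec
    key = spec.strip()
    if key.lower() in _PRESETS:
        return _PRESETS[key.lower()]
    return element_material(key)
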