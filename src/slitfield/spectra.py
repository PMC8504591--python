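"""X-ray spectra: a semi-empirical generator and a file loader.

The generator uses a Kramers-type bremsstrahlung shape, intensity
proportional to ``(E_max - E) / E`` on a 0.5 keV grid, hardened by the listed
filters via ``exp(-sum mu_i t_i)``.  Characteristic anode lines are not
modelled; for the foil-ranking use of these spectra the argmax is insensitive
to that level of spectral detail, and externally computed spectra can be
loaded from text files when higher fidelity is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attenuation import mu_linear
from .errors import ConfigurationError, EnergyRangeError
from .materials import MaterialComposition, resolve_material

KVP_MIN = 20.0
KVP_MAX = 150.0
GRID_STEP_KEV = 0.5


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin.

    ``energies`` is an ascending keV grid and ``weights`` the dimensionless
    relative photon counts per bin (non-negative, at least one positive).
    """

    energies: np.ndarray  # keV
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape or e.size == 0:
            raise ValueError("energies and weights must be equal-length 1D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly ascending")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean energy, keV."""
        return float(np.sum(self.energies * self.weights) / np.sum(self.weights))

    @property
    def max_energy(self) -> float:
        """Highest energy with non-zero weight, keV."""
        return float(self.energies[self.weights > 0][-1])

    def normalized(self) -> "Spectrum":
        return Spectrum(
            self.energies, self.weights / np.sum(self.weights), self.provenance
        )


def generate_spectrum(
    kvp: float,
    target: str = "W",
    filters: (
        list[tuple[str | MaterialComposition, float]] | None
    ) = None,
) -> Spectrum:
    """Generate a filtered bremsstrahlung spectrum.

    Parameters
    ----------
    kvp : tube potential in kV (20-150).
    target : anode element label; recorded in the provenance only, since no
        characteristic lines are generated.
    filters : list of ``(material, thickness_um)``; materials may be element
        symbols, preset names or :class:`MaterialComposition`.

    The result is normalized to unit total weight.  The maximum energy bin
    never exceeds the tube potential.
    """
    if not KVP_MIN <= kvp <= KVP_MAX:
        raise EnergyRangeError(f"kvp must be within [{KVP_MIN}, {KVP_MAX}] kV")
    energies = np.arange(1.0, kvp + 1e-9, GRID_STEP_KEV)
    weights = np.maximum(kvp - energies, 0.0) / energies
    labels = []
    for spec, t_um in filters or []:
        material = resolve_material(spec)
        mu = mu_linear(material, energies, "total")
        weights = weights * np.exp(-mu * t_um * 1e-4)
        labels.append(f"{material.name}:{t_um:g}um")
    provenance = f"generated {kvp:g}kVp {target}" + (
        " + " + " + ".join(labels) if labels else ""
    )
    return Spectrum(energies, weights / weights.sum(), provenance)


def load_spectrum(path: str | Path) -> Spectrum:
    """Load a two-column (energy keV, relative fluence) text spectrum.

    Whitespace or comma separated; ``#`` starts a comment.
    """
    path = Path(path)
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ConfigurationError(f"{path}: bad spectrum line {raw!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ConfigurationError(f"{path}: no spectrum data found")
    arr = np.array(sorted(rows))
    w = arr[:, 1]
    return Spectrum(arr[:, 0], w / w.sum(), provenance=f"file:{path.name}")


def save_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {spectrum.provenance}", "# energy_kev  relative_fluence"]
    lines += [
        f"{e:.4f}  {w:.8g}"
        for e, w in zip(spectrum.energies, spectrum.weights)
    ]
    path.write_text("\n".join(lines) + "\n")
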