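"""Exception hierarchy for the slitfield package.

All errors derive from :class:`SlitFieldError` so callers (and the CLI) can
map failure categories onto distinct exit codes.
"""


class SlitFieldError(Exception):
    """Base class for all slitfield errors."""


class EnergyRangeError(SlitFieldError, ValueError):
    """Photon energy outside the tabulated 1-150 keV range."""


class ElementLookupError(SlitFieldError, LookupError):
    """Element not present in the packaged attenuation tables."""


class DegenerateGeometryError(SlitFieldError, ValueError):
    """Slit-camera geometry with no solvable projection (e.g. foil at source height)."""


class ConfigurationError(SlitFieldError, ValueError):
    """Invalid or incomplete configuration (rulesets, scenario, CLI inputs)."""


class NoEdgeError(SlitFieldError, RuntimeError):
    """No falling fluorescence flank found in the profile (flat / unirradiated image)."""


class InsufficientDataError(SlitFieldError, RuntimeError):
    """Fewer than three profile samples available for the edge fit."""


class ProfileDataError(SlitFieldError, ValueError):
    """Profile data unusable (e.g. non-positive minimum inside the camera window)."""
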