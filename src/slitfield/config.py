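"""YAML/JSON configuration loading for geometry, limits, profiles, scenarios."""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigurationError
from .geometry import ComplianceLimits, SlitGeometry
from .profiles import ProfileConfig
from .synth import ScenarioConfig


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def geometry_from_dict(d: dict) -> SlitGeometry:
    try:
        return SlitGeometry(
            y_foil=float(d["y_foil_mm"]),
            y_slit=float(d["y_slit_mm"]),
            x_slit=float(d["x_slit_mm"]),
            y_source=float(d["y_source_mm"]),
            x_source=float(d["x_source_mm"]),
            side=d.get("side", "chest_wall"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"geometry config missing key {exc}") from exc


def load_geometry(path: str | Path) -> SlitGeometry:
    return geometry_from_dict(_load_mapping(path))


def load_limits(path: str | Path | None) -> ComplianceLimits:
    if path is None:
        return ComplianceLimits()
    d = _load_mapping(path)
    return ComplianceLimits(
        sid_fraction=float(d.get("sid_fraction", 0.02)),
        eu_limit_mm=float(d.get("eu_limit_mm", 5.0)),
        congruence_sid_fraction=float(d.get("congruence_sid_fraction", 0.02)),
    )


def load_profile_config(path: str | Path | None) -> ProfileConfig:
    if path is None:
        return ProfileConfig()
    d = _load_mapping(path)
    window = d.get("camera_window_mm")
    return ProfileConfig(
        roi_width=int(d.get("roi_width", 500)),
        smooth_width=int(d.get("smooth_width", 5)),
        camera_window=tuple(float(v) for v in window) if window else None,
        fit_fraction_low=float(d.get("fit_fraction_low", 0.15)),
        fit_fraction_high=float(d.get("fit_fraction_high", 0.85)),
        roi_center=(int(d["roi_center"]) if "roi_center" in d else None),
    )


def scenario_from_dict(d: dict) -> ScenarioConfig:
    geom = geometry_from_dict(d.get("geometry", d))
    kwargs = {}
    simple = {
        "x_fov_true_mm": "x_fov_true",
        "pixel_pitch_mm": "pixel_pitch_mm",
        "plateau_adu": "plateau_adu",
        "background_adu": "background_adu",
        "offset_adu": "offset_adu",
        "bit_depth": "bit_depth",
        "focal_spot_mm": "focal_spot_mm",
        "slit_aperture_mm": "slit_aperture_mm",
        "brass_transmission": "brass_transmission",
        "foil_end_step": "foil_end_step",
        "foil_end_step_adu": "foil_end_step_adu",
        "direct_slit_transmission": "direct_slit_transmission",
        "binning": "binning",
        "orientation": "orientation",
        "seed": "seed",
        "direct_beam_adu": "direct_beam_adu",
    }
    for key, attr in simple.items():
        if key in d:
            kwargs[attr] = d[key]
    if "x_fov_true" not in kwargs:
        raise ConfigurationError("scenario config requires x_fov_true_mm")
    for key, attr in [
        ("image_shape", "image_shape"),
        ("foil_extent_mm", "foil_extent_mm"),
        ("camera_span_mm", "camera_span_mm"),
    ]:
        if key in d and d[key] is not None:
            kwargs[attr] = tuple(d[key])
    return ScenarioConfig(geom=geom, **kwargs)


def load_scenario(path: str | Path) -> ScenarioConfig:
    return scenario_from_dict(_load_mapping(path))
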