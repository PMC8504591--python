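"""Synthetic slit-camera projection scenes with known ground truth.

The renderer builds the expected-value image from the same similar-triangle
geometry the measurement inverts: the irradiated part of the foil, as limited
by the true field boundary ``x_fov_true``, is projected through the slit onto
the detector, producing a fluorescence band whose falling flank reaches the
in-camera baseline exactly at the true edge position ``x_edge_true``.  The
flank is the convolution of a step with two boxes - the projected slit
aperture and the focal-spot penumbra - i.e. a trapezoid.  Pixel values are
then drawn as Poisson counts on top of a deterministic detector offset and
clipped to the detector bit depth.

ADU levels default to the clinical observations for this class of system:
~50 ADU detector offset, ~100 ADU scattered background inside the camera
shadow, ~150 ADU where fluorescence is present, 14-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError
from .geometry import SlitGeometry, invert_fov_boundary
from .profiles import (
    LineProfile,
    ProfileConfig,
    ProjectionImage,
    default_camera_window,
    extract_profile,
    normalize_profile,
    smooth_profile,
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to render one synthetic acquisition."""

    geom: SlitGeometry
    x_fov_true: float  # mm; negative = beyond the detector
    image_shape: tuple[int, int] = (600, 2048)  # (roi axis, measurement axis)
    pixel_pitch_mm: float = 0.070
    plateau_adu: float = 150.0  # total level inside the fluorescence band
    background_adu: float = 100.0  # scatter component above the offset, outside camera
    offset_adu: float = 50.0  # deterministic detector offset
    bit_depth: int = 14
    focal_spot_mm: float = 0.35
    slit_aperture_mm: float = 1.0
    foil_extent_mm: tuple[float, float] = (-40.0, 60.0)  # at the foil plane
    brass_transmission: float = 0.5  # scatter surviving the camera top plate
    camera_span_mm: tuple[float, float] | None = None  # top-plate shadow; auto
    direct_beam_adu: float | None = None  # level outside the camera; auto
    foil_end_step: bool = False
    foil_end_step_adu: float = 40.0
    direct_slit_transmission: bool = False
    binning: int = 1  # 2 emulates DBT 2x2 binning (sum, pitch doubled)
    orientation: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.plateau_adu > self.background_adu > self.offset_adu >= 0):
            raise ConfigurationError("need plateau > background > offset >= 0 ADU")
        if self.focal_spot_mm < 0:
            raise ConfigurationError("focal spot size must be >= 0")
        if self.binning not in (1, 2):
            raise ConfigurationError("binning must be 1 or 2")
        if not 0 < self.brass_transmission <= 1:
            raise ConfigurationError("brass transmission must be in (0, 1]")
        if self.foil_extent_mm[0] >= self.foil_extent_mm[1]:
            raise ConfigurationError("foil extent must be a non-empty interval")

    @property
    def camera_span(self) -> tuple[float, float]:
        if self.camera_span_mm is not None:
            return self.camera_span_mm
        return (self.geom.x_slit - 30.0, self.geom.x_slit + 70.0)


@dataclass(frozen=True)
class RenderAudit:
    """Ground truth and analytic expectations recorded with every render."""

    x_edge_true: float  # mm
    x_fov_true: float
    penumbra_width_mm: float
    slit_blur_mm: float
    band_mm: tuple[float, float]  # fluorescence band (start, edge foot)
    camera_span_mm: tuple[float, float]
    region_means_adu: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "x_edge_true_mm": self.x_edge_true,
            "x_fov_true_mm": self.x_fov_true,
            "penumbra_width_mm": self.penumbra_width_mm,
            "slit_blur_mm": self.slit_blur_mm,
            "band_mm": list(self.band_mm),
            "camera_span_mm": list(self.camera_span_mm),
            "region_means_adu": dict(self.region_means_adu),
            "seed": self.seed,
        }


def foil_to_image(geom: SlitGeometry, u_foil: float) -> float:
    """Project a foil-plane position through the slit onto the detector (mm)."""
    if geom.y_foil <= geom.y_slit:
        raise DegenerateGeometryError("foil must be above the slit")
    m = geom.y_slit / (geom.y_foil - geom.y_slit)
    return geom.x_slit + (geom.x_slit - u_foil) * m


def field_edge_at_foil(geom: SlitGeometry, x_fov: float) -> float:
    """Field-boundary position at the foil plane, from the source ray through
    the boundary point at the detector plane."""
    frac = geom.y_foil / geom.y_source
    return geom.x_source + (x_fov - geom.x_source) * (1.0 - frac)


def penumbra_width(geom: SlitGeometry, focal_spot_mm: float) -> float:
    """Focal-spot penumbra of the field edge as projected into the camera, mm.

    The boundary is anchored at the detector plane; a source of lateral
    extent f spreads the boundary at the foil plane over f * y_foil/y_source,
    which the slit magnifies onto the detector by y_slit/(y_foil - y_slit).
    Zero for a point focal spot or a foil on the detector plane.
    """
    if focal_spot_mm < 0:
        raise ConfigurationError("focal spot size must be >= 0")
    if geom.y_foil == 0:
        return 0.0
    if geom.y_foil <= geom.y_slit:
        raise DegenerateGeometryError("foil must be above the slit")
    m = geom.y_slit / (geom.y_foil - geom.y_slit)
    return focal_spot_mm * (geom.y_foil / geom.y_source) * m


def slit_blur_width(geom: SlitGeometry, aperture_mm: float) -> float:
    """Blur of a foil-plane point due to the finite slit aperture, mm."""
    if geom.y_foil <= geom.y_slit:
        raise DegenerateGeometryError("foil must be above the slit")
    return aperture_mm * geom.y_foil / (geom.y_foil - geom.y_slit)


def _box_box_cdf(s: np.ndarray, a: float, b: float) -> np.ndarray:
    """CDF of the convolution of two centered boxes of widths a >= b."""
    if a < b:
        a, b = b, a
    if a == 0:
        return (s >= 0).astype(float)
    if b == 0:
        return np.clip(s / a + 0.5, 0.0, 1.0)
    half = (a + b) / 2.0
    flat = (a - b) / 2.0
    out = np.empty_like(s)
    out[s <= -half] = 0.0
    out[s >= half] = 1.0
    rise = (s > -half) & (s < -flat)
    out[rise] = (s[rise] + half) ** 2 / (2 * a * b)
    mid = (s >= -flat) & (s <= flat)
    out[mid] = 0.5 + s[mid] / a
    fall = (s > flat) & (s < half)
    out[fall] = 1.0 - (half - s[fall]) ** 2 / (2 * a * b)
    return out


def expected_profile(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, RenderAudit]:
    """Noise-free expected ADU along the measurement axis, plus the audit."""
    geom = config.geom
    n_pos = config.image_shape[1]
    pos = np.arange(n_pos) * config.pixel_pitch_mm
    extent = pos[-1]

    x_edge = invert_fov_boundary(geom, config.x_fov_true)
    if not 0 < x_edge < extent:
        raise ConfigurationError(
            f"projected edge at {x_edge:.1f} mm falls outside the image (0-{extent:.1f})"
        )
    cam_lo, cam_hi = config.camera_span
    pen = penumbra_width(geom, config.focal_spot_mm)
    blur = slit_blur_width(geom, config.slit_aperture_mm)

    u0, u1 = config.foil_extent_mm
    band_start = foil_to_image(geom, u1)
    foil_end = foil_to_image(geom, u0)  # no foil projected beyond this

    # background_adu is the scatter component on top of the offset outside the
    # camera; under the top plate it is reduced by the brass transmission
    baseline_cam = config.offset_adu + config.background_adu * config.brass_transmission
    fluor_amp = config.plateau_adu - baseline_cam
    if fluor_amp <= 0:
        raise ConfigurationError(
            "plateau level must exceed the in-camera baseline "
            f"({baseline_cam:.1f} ADU)"
        )
    outside = (
        config.direct_beam_adu
        if config.direct_beam_adu is not None
        else config.offset_adu + config.background_adu
    )

    mean = np.full(n_pos, outside, dtype=float)
    in_cam = (pos >= cam_lo) & (pos <= cam_hi)
    mean[in_cam] = baseline_cam

    # lead back-plate region: offset only, 50 mm beyond the camera
    lead = (pos > cam_hi) & (pos <= cam_hi + 50.0)
    mean[lead] = config.offset_adu

    # fluorescence band: rises at the projected foil end, falls so the flank
    # foot (signal vanishing point) sits exactly at x_edge_true
    rise = _box_box_cdf(pos - band_start, blur, pen)
    c_fall = x_edge - (blur + pen) / 2.0
    fall = 1.0 - _box_box_cdf(pos - c_fall, blur, pen)
    band = rise * fall
    mean[in_cam] += fluor_amp * band[in_cam]

    if config.foil_end_step:
        step = _box_box_cdf(pos - foil_end, blur, pen)
        mean[in_cam] += config.foil_end_step_adu * step[in_cam]
    if config.direct_slit_transmission:
        bump = _box_box_cdf(pos - (geom.x_slit - 1.0), blur, 0.0) * (
            1.0 - _box_box_cdf(pos - (geom.x_slit + 1.0), blur, 0.0)
        )
        mean[in_cam] += 5.0 * fluor_amp * bump[in_cam]

    audit = RenderAudit(
        x_edge_true=x_edge,
        x_fov_true=config.x_fov_true,
        penumbra_width_mm=pen,
        slit_blur_mm=blur,
        band_mm=(band_start, x_edge),
        camera_span_mm=(cam_lo, cam_hi),
        region_means_adu={
            "outside_camera": outside,
            "lead_plate": config.offset_adu,
            "camera_baseline": baseline_cam,
            "plateau": config.plateau_adu,
        },
        seed=config.seed,
    )
    return pos, mean, audit


def render_scene(
    config: ScenarioConfig, noise: bool = True
) -> tuple[ProjectionImage, RenderAudit]:
    """Render a synthetic projection image; deterministic for a fixed seed."""
    _, mean, audit = expected_profile(config)
    n_roi, n_pos = config.image_shape
    vmax = 2**config.bit_depth - 1
    img = np.broadcast_to(mean, (n_roi, n_pos))
    if noise:
        rng = np.random.default_rng(config.seed)
        img = config.offset_adu + rng.poisson(
            np.maximum(img - config.offset_adu, 0.0)
        ).astype(float)
    pitch = config.pixel_pitch_mm
    if config.binning == 2:
        if n_roi % 2 or n_pos % 2:
            raise ConfigurationError("2x2 binning needs even image dimensions")
        img = img.reshape(n_roi // 2, 2, n_pos // 2, 2).sum(axis=(1, 3))
        pitch *= 2.0
    pixels = np.clip(np.rint(img), 0, vmax).astype(np.uint16)
    if config.orientation == "right":
        pixels = pixels[:, ::-1]
    elif config.orientation == "top":
        pixels = pixels.T
    elif config.orientation == "bottom":
        pixels = pixels.T[::-1, :]
    image = ProjectionImage(
        pixels, pitch, bit_depth=config.bit_depth, orientation=config.orientation
    )
    return image, audit


def render_profile_set(
    configs: list[ScenarioConfig], profile_config: ProfileConfig | None = None
) -> list[LineProfile]:
    """Render several views and return their independently normalized
    line profiles (the multi-view comparison figure)."""
    sides = {c.geom.side for c in configs}
    if len(sides) > 1:
        raise ConfigurationError("profile sets must share a detector side")
    out = []
    for cfg in configs:
        image, _ = render_scene(cfg)
        pc = profile_config or ProfileConfig()
        window = pc.camera_window or default_camera_window(cfg.geom)
        prof = extract_profile(image, pc)
        prof = smooth_profile(prof, pc.smooth_width)
        prof = normalize_profile(prof, window)
        out.append(prof)
    return out
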