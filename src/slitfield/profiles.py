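"""From projection image to edge position: ROI integration, smoothing,
normalization and linear-fit extrapolation.

The measurement integrates a wide region of interest into a 1D line profile
(summing perpendicular to the measurement axis), smooths it with a short mean
filter, normalizes it to its minimum inside the camera shadow, and fits an
ordinary least-squares line to the steep intensity fall between the
fluorescence plateau and the baseline.  The edge position ``x_edge`` is where
the fitted line extrapolates back to the baseline value of 1 - the point
where the fluorescence signal vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    NoEdgeError,
    ProfileDataError,
)
from .geometry import FieldMeasurement, SlitGeometry, fov_boundary

ORIENTATIONS = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class ProjectionImage:
    """Raw ("for processing") detector image plus acquisition metadata.

    ``orientation`` names the image edge that touches the detector-side
    origin: 'left'/'right' for a measurement axis along columns, 'top'/
    'bottom' along rows.
    """

    pixels: np.ndarray  # 2D, non-negative ADU
    pixel_pitch_mm: float
    bit_depth: int = 14
    orientation: str = "left"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if px.size and px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values exceed the {self.bit_depth}-bit range"
            )
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the profile extraction and edge fit.

    ``camera_window`` is the (lo, hi) interval in mm that lies inside the
    camera shadow; the normalization minimum and the edge search are
    restricted to it.  ``fit_fraction_low/high`` select the fractional-height
    band of the plateau-to-baseline drop used for the linear fit.
    """

    roi_width: int = 500
    smooth_width: int = 5
    camera_window: tuple[float, float] | None = None
    fit_fraction_low: float = 0.15
    fit_fraction_high: float = 0.85
    roi_center: int | None = None  # index along the ROI axis; image center if None

    def __post_init__(self) -> None:
        if self.roi_width < 1:
            raise ConfigurationError("roi_width must be >= 1")
        if self.smooth_width < 1 or self.smooth_width % 2 == 0:
            raise ConfigurationError("smooth_width must be odd and >= 1")
        if not 0 <= self.fit_fraction_low < self.fit_fraction_high <= 1:
            raise ConfigurationError("need 0 <= low < high <= 1 fit fractions")


@dataclass(frozen=True)
class LineProfile:
    """Integrated 1D signal: positions (mm from the detector-side origin),
    raw intensity (ADU) and, once normalized, the dimensionless intensity
    whose minimum inside the camera window equals 1."""

    positions_mm: np.ndarray  # strictly increasing
    raw: np.ndarray
    normalized: np.ndarray | None = None
    camera_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))


@dataclass(frozen=True)
class EdgeFit:
    """OLS line fitted to the falling flank and its extrapolated edge."""

    slope: float  # 1/mm
    intercept: float
    r_squared: float
    window: tuple[int, int]  # [start, stop) index range of the fit
    x_edge: float  # mm
    plateau: float  # normalized plateau level


def extract_profile(image: ProjectionImage, config: ProfileConfig) -> LineProfile:
    """Integrate ``roi_width`` pixels across the slit into a line profile.

    Positions are in mm from the detector-side origin named by the image
    orientation; position 0 is the center of the origin row/column.
    """
    px = image.pixels
    if image.orientation in ("left", "right"):
        data = px if image.orientation == "left" else px[:, ::-1]
        n_roi, n_pos = data.shape
    else:
        data = px if image.orientation == "top" else px[::-1, :]
        data = data.T
        n_roi, n_pos = data.shape
    center = config.roi_center if config.roi_center is not None else n_roi // 2
    lo = center - config.roi_width // 2
    hi = lo + config.roi_width
    if lo < 0 or hi > n_roi:
        raise ConfigurationError(
            f"ROI of width {config.roi_width} at center {center} "
            f"exceeds the image extent {n_roi}"
        )
    raw = data[lo:hi, :].sum(axis=0, dtype=np.int64).astype(float)
    positions = np.arange(n_pos) * image.pixel_pitch_mm
    return LineProfile(positions, raw, camera_window=config.camera_window)


def smooth_profile(profile: LineProfile, width: int = 5) -> LineProfile:
    """Moving-mean filter with truncated windows at the array ends.

    Truncation (rather than reflection) avoids inventing signal beyond the
    detector edge.  Positions are unchanged.
    """
    if width % 2 == 0 or width < 1:
        raise ConfigurationError("smoothing width must be odd and >= 1")
    kernel = np.ones(width)
    num = np.convolve(profile.raw, kernel, mode="same")
    den = np.convolve(np.ones_like(profile.raw), kernel, mode="same")
    return replace(profile, raw=num / den, normalized=None)


def normalize_profile(
    profile: LineProfile, camera_window: tuple[float, float]
) -> LineProfile:
    """Normalize to the minimum raw intensity inside the camera window."""
    lo, hi = camera_window
    mask = (profile.positions_mm >= lo) & (profile.positions_mm <= hi)
    if not np.any(mask):
        raise ConfigurationError("camera window does not overlap the profile")
    floor = profile.raw[mask].min()
    if floor <= 0:
        raise ProfileDataError(
            "non-positive minimum inside the camera window (dead ROI?)"
        )
    return replace(
        profile, normalized=profile.raw / floor, camera_window=(lo, hi)
    )


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """[start, stop) of the longest contiguous True run, or None."""
    best = None
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None:
        i = len(mask)
        if best is None or i - start > best[1] - best[0]:
            best = (start, i)
    return best


def fit_edge(
    profile: LineProfile,
    config: ProfileConfig,
    search_direction: str = "increasing",
) -> EdgeFit:
    """Locate the edge by extrapolating a line fitted to the steep fall.

    The fluorescence plateau is estimated as the median of the longest
    contiguous above-baseline run inside the camera window; the fit window is
    the contiguous flank whose normalized values lie in the fractional-height
    band [low, high] of the plateau-to-baseline drop, on the side of the
    plateau given by ``search_direction`` ('increasing' = edge at larger
    positions).  ``x_edge`` solves ``slope * x + intercept = 1``.
    """
    if profile.normalized is None:
        raise ConfigurationError("profile must be normalized before fitting")
    if search_direction not in ("increasing", "decreasing"):
        raise ConfigurationError("search_direction: 'increasing' or 'decreasing'")
    window = config.camera_window or profile.camera_window
    if window is None:
        raise ConfigurationError("no camera window configured")

    pos = profile.positions_mm
    vals = profile.normalized
    if search_direction == "decreasing":
        pos = -pos[::-1]
        vals = vals[::-1]
        window = (-window[1], -window[0])

    sel = np.nonzero((pos >= window[0]) & (pos <= window[1]))[0]
    if sel.size < 3:
        raise InsufficientDataError("camera window contains fewer than 3 samples")
    p = pos[sel]
    v = vals[sel]

    vmax = float(np.percentile(v, 98))
    if vmax - 1.0 < 0.02:
        raise NoEdgeError("no fluorescence plateau above the baseline")
    run = _longest_true_run(v > 1.0 + 0.5 * (vmax - 1.0))
    if run is None:
        raise NoEdgeError("no contiguous above-baseline run found")
    plateau = float(np.median(v[run[0] : run[1]]))

    drop = plateau - 1.0
    hi_thr = 1.0 + config.fit_fraction_high * drop
    lo_thr = 1.0 + config.fit_fraction_low * drop

    # First crossing below the low threshold after the plateau run
    after = np.nonzero(v[run[1] :] <= lo_thr)[0]
    if after.size == 0:
        raise NoEdgeError("profile never falls to the baseline inside the window")
    i_low = run[1] + after[0]
    # Last sample at or above the high threshold before that crossing
    before = np.nonzero(v[:i_low] >= hi_thr)[0]
    i_high = before[-1] if before.size else 0

    idx = np.arange(i_high + 1, i_low)
    idx = idx[(v[idx] <= hi_thr) & (v[idx] >= lo_thr)]
    if idx.size < 3:
        raise InsufficientDataError(
            f"only {idx.size} samples on the falling flank (need >= 3)"
        )
    x = p[idx]
    y = v[idx]
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if slope == 0:
        raise NoEdgeError("flank fit has zero slope")
    x_edge = (1.0 - intercept) / slope
    if search_direction == "decreasing":
        x_edge = -x_edge
        slope = -slope
        intercept = 1.0 - slope * x_edge  # re-express in original coordinates
    lo_i, hi_i = int(sel[idx[0]]), int(sel[idx[-1]]) + 1
    if search_direction == "decreasing":
        n = profile.positions_mm.size
        lo_i, hi_i = n - hi_i, n - lo_i
    return EdgeFit(float(slope), float(intercept), r2, (lo_i, hi_i),
                   float(x_edge), plateau)


@dataclass(frozen=True)
class FieldMeasurementResult:
    """A field measurement plus the intermediate profile and fit for audit."""

    measurement: FieldMeasurement
    profile: LineProfile
    fit: EdgeFit


def default_camera_window(geom: SlitGeometry) -> tuple[float, float]:
    """Camera-shadow interval used when none is configured: the 100 mm top
    plate with the slit 30 mm from its leading edge, inset by a 5 mm margin."""
    return (geom.x_slit - 25.0, geom.x_slit + 65.0)


def measure_field(
    image: ProjectionImage,
    geom: SlitGeometry,
    config: ProfileConfig | None = None,
    view: str = "",
    search_direction: str = "increasing",
) -> FieldMeasurementResult:
    """Full pipeline: extract, smooth, normalize, fit, apply the boundary
    formula.  Returns the measurement together with the audit trail."""
    if config is None:
        config = ProfileConfig()
    window = config.camera_window or default_camera_window(geom)
    profile = extract_profile(image, config)
    profile = smooth_profile(profile, config.smooth_width)
    profile = normalize_profile(profile, window)
    fit = fit_edge(profile, config, search_direction)
    x_fov = fov_boundary(geom, fit.x_edge)
    meas = FieldMeasurement(
        view=view or "unnamed", x_edge=fit.x_edge, x_fov=x_fov, side=geom.side
    )
    return FieldMeasurementResult(meas, profile, fit)
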