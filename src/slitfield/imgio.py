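"""Image and profile I/O: DICOM / 16-bit TIFF / PNG input, TIFF output,
profile CSV export and fit-audit JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .profiles import EdgeFit, LineProfile, ProjectionImage


def load_image(
    path: str | Path,
    pixel_pitch_mm: float | None = None,
    orientation: str = "left",
    bit_depth: int = 14,
) -> ProjectionImage:
    """Load a projection image from DICOM, TIFF or PNG.

    For DICOM the pixel pitch is read from ImagerPixelSpacing / PixelSpacing
    when present; an explicit ``pixel_pitch_mm`` always wins.  TIFF and PNG
    carry no trusted pitch metadata, so the pitch is required for them.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
        if pixel_pitch_mm is None:
            spacing = getattr(ds, "ImagerPixelSpacing", None) or getattr(
                ds, "PixelSpacing", None
            )
            if spacing is None:
                raise ConfigurationError(
                    f"{path}: no pixel spacing in DICOM header; pass pixel_pitch_mm"
                )
            pixel_pitch_mm = float(spacing[0])
        bits = getattr(ds, "BitsStored", None)
        if bits is not None:
            bit_depth = int(bits)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    elif suffix == ".png":
        from PIL import Image

        pixels = np.asarray(Image.open(path))
    else:
        raise ConfigurationError(f"unsupported image format: {path.name}")
    if pixel_pitch_mm is None:
        raise ConfigurationError(f"{path}: pixel pitch required for {suffix} input")
    return ProjectionImage(
        np.asarray(pixels), pixel_pitch_mm, bit_depth=bit_depth,
        orientation=orientation,
    )


def save_image_tiff(image: ProjectionImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), image.pixels.astype(np.uint16))


def export_profile_csv(profile: LineProfile, path: str | Path) -> None:
    """Write (position_mm, raw, normalized) columns as CSV."""
    norm = (
        profile.normalized
        if profile.normalized is not None
        else np.full_like(profile.raw, np.nan)
    )
    header = "position_mm,raw,normalized"
    data = np.column_stack([profile.positions_mm, profile.raw, norm])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def export_fit_json(fit: EdgeFit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope_per_mm": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "fit_window": list(fit.window),
                "x_edge_mm": fit.x_edge,
                "plateau": fit.plateau,
            },
            indent=2,
        )
    )
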