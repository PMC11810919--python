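"""CT slice preparation: Hounsfield conversion, window/level contrast,
contrast-limited adaptive histogram equalization (CLAHE), min–max
normalization.

The chain mirrors standard abdominal CT practice: stored pixel values are
mapped to Hounsfield units (HU) through the scanner's affine rescale, a
soft-tissue window picks out the liver/gallbladder intensity band, CLAHE
boosts local contrast at the organ boundary, and the result is normalized to
[0, 1] for the network.

Window defaults (level 60 HU, width 400 HU) are a common abdominal
soft-tissue window; CLAHE defaults (clip limit 0.01, 8x8 tiles) match the
scikit-image convention.  Both are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import exposure


class InputError(ValueError):
    """Invalid image input (non-finite values, empty grid, shape mismatch)."""


class WindowError(ValueError):
    """Invalid window or CLAHE specification."""


@dataclass
class RawSlice:
    """Stored pixel values plus the scanner's rescale to Hounsfield units."""

    pixels: np.ndarray
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("pixel grid must be 2D and non-empty")
        if self.rescale_slope <= 0:
            raise InputError("rescale slope must be positive")


@dataclass
class WindowSpec:
    """Window level (center, HU) and width (HU) of the displayed band."""

    level: float = 60.0
    width: float = 400.0

    def __post_init__(self):
        if not np.isfinite(self.level) or not np.isfinite(self.width):
            raise WindowError("window level/width must be finite")
        if self.width <= 0:
            raise WindowError("window width must be positive")


def to_hounsfield(raw: RawSlice) -> np.ndarray:
    """Affine rescale of stored values to HU: ``pixels * slope + intercept``."""
    if not (np.isfinite(raw.rescale_slope) and np.isfinite(raw.rescale_intercept)):
        raise InputError("rescale slope/intercept must be finite")
    return raw.pixels.astype(np.float64) * raw.rescale_slope + raw.rescale_intercept


def apply_window(hu: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Clip HU values to [level - width/2, level + width/2] and map to [0, 1].

    Monotone non-decreasing in the HU value for a fixed window.
    """
    hu = np.asarray(hu, dtype=np.float64)
    lo = window.level - window.width / 2.0
    return np.clip((hu - lo) / window.width, 0.0, 1.0)


def equalize_adaptive(
    img: np.ndarray, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    ``tile_grid`` is the number of tiles per axis; it is translated to the
    scikit-image kernel size.  A (near-)constant image is returned unchanged —
    there is no contrast to enhance and equalizing it is numerically
    ill-posed.
    """
    if clip_limit <= 0:
        raise WindowError("CLAHE clip limit must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise InputError("CLAHE input must lie in [0, 1]")
    if np.ptp(img) < 1e-9:
        return img.copy()
    kernel = (max(1, img.shape[0] // tile_grid[0]), max(1, img.shape[1] // tile_grid[1]))
    return exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit)


def normalize01(img: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant grid maps to all zeros.

    The constant-grid policy keeps padding-only slices from aborting a batch.
    Idempotent on its own output.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise InputError("cannot normalize an empty grid")
    if not np.all(np.isfinite(img)):
        raise InputError("cannot normalize non-finite values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def preprocess_slice(
    raw: RawSlice,
    window: WindowSpec = WindowSpec(),
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """The full chain: HU conversion -> windowing -> CLAHE -> [0, 1] rescale."""
    hu = to_hounsfield(raw)
    win = apply_window(hu, window)
    eq = equalize_adaptive(win, clip_limit=clip_limit, tile_grid=tile_grid)
    return normalize01(eq)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_png(path) -> RawSlice:
    """8/16-bit grayscale PNG; slope 1, intercept 0 (the HU step is identity)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return RawSlice(arr.astype(np.float64), 1.0, 0.0)


def read_nifti_slices(path, axis: int = 2) -> list[RawSlice]:
    """Per-slice extraction from a NIfTI volume along the axial axis.

    nibabel applies the NIfTI scaling on read, so the returned values are
    already HU and slope/intercept are identity.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).get_fdata())
    vol = np.moveaxis(vol, axis, 0)
    return [RawSlice(sl.astype(np.float64), 1.0, 0.0) for sl in vol]


def read_dicom(path) -> RawSlice:
    """Single-frame DICOM using the RescaleSlope/RescaleIntercept tags."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return RawSlice(ds.pixel_array.astype(np.float64), slope, intercept)


def write_png(path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16))


def write_nifti(path, img: np.ndarray) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), np.eye(4)), str(path))


def write_sidecar(
    path,
    window: WindowSpec,
    clip_limit: float,
    tile_grid: tuple[int, int],
) -> None:
    """Echo the preprocessing parameters next to the outputs as JSON."""
    Path(path).write_text(
        json.dumps(
            {
                "window_level": window.level,
                "window_width": window.width,
                "clahe_clip_limit": clip_limit,
                "clahe_tile_grid": list(tile_grid),
            },
            indent=2,
        )
    )
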