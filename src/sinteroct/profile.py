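"""Reflectivity-profile extraction from en-face OCT images.

An en-face (constant-depth) OCT image of a sintered ceramic shows the
granulation as bright texture, with the dark/bright banding oriented
parallel to the y-axis.  Averaging all image rows gives the raw
reflectivity profile rho(x); a moving-average smoothing produces the
averaged graph that the piecewise models describe.  A fixed-threshold
binarization with connected-component counting quantifies the number of
resolved bright features (the granulation count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EnFaceImage",
    "BinaryImage",
    "ReflectivityProfile",
    "AcquisitionGeometry",
    "load_image",
    "save_image",
    "orient_bands",
    "binarize",
    "count_grains",
    "extract_profile",
    "smooth_profile",
    "default_smoothing_window",
    "air_to_material_depth",
    "profile_to_csv",
    "profile_from_csv",
]

DEFAULT_EXTENT_MM = 3.25
DEFAULT_THRESHOLD = 127


@dataclass
class EnFaceImage:
    """8-bit grayscale en-face OCT raster with its lateral physical extent."""

    pixels: np.ndarray
    extent_x_mm: float = DEFAULT_EXTENT_MM
    extent_y_mm: float = DEFAULT_EXTENT_MM

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("expected a 2-D single-channel image")
        if p.dtype != np.uint8:
            if np.issubdtype(p.dtype, np.integer) and p.min() >= 0 and p.max() <= 255:
                p = p.astype(np.uint8)
            else:
                raise ValueError("expected 8-bit gray levels in [0, 255]")
        self.pixels = p
        if self.extent_x_mm <= 0 or self.extent_y_mm <= 0:
            raise ValueError("lateral extents must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """0/1 raster plus the threshold it came from."""

    pixels: np.ndarray
    threshold: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if not np.isin(p, (0, 1)).all():
            raise ValueError("binary image may contain only 0 and 1")
        self.pixels = p.astype(np.uint8)


@dataclass
class ReflectivityProfile:
    """Reflectivity (gray levels) versus lateral position x (mm).

    ``window`` records the moving-average length of a smoothed profile
    (None for raw data); model selection uses it to discount the sample
    count for the correlation smoothing introduces.
    """

    x: np.ndarray
    rho: np.ndarray
    kind: str = "raw"  # "raw" | "smoothed"
    window: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.x.shape != self.rho.shape or self.x.ndim != 1:
            raise ValueError("x and rho must be matching 1-D arrays")
        if self.x.size >= 2 and np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.kind not in ("raw", "smoothed"):
            raise ValueError("kind must be 'raw' or 'smoothed'")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Axial geometry of the acquisition.

    ``n`` is the sample's group refractive index (approx. 1.5 for dental
    ceramics at 1060 nm); depths are measured in air.
    """

    n: float = 1.5
    axial_range_air_mm: float = 3.75
    enface_depth_air_mm: float = 0.375

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.axial_range_air_mm <= 0 or self.enface_depth_air_mm <= 0:
            raise ValueError("depths must be positive")
        if self.enface_depth_air_mm > self.axial_range_air_mm:
            raise ValueError("en-face depth cannot exceed the axial range")

    @property
    def axial_range_material_mm(self) -> float:
        return air_to_material_depth(self.axial_range_air_mm, self.n)

    @property
    def enface_depth_material_mm(self) -> float:
        return air_to_material_depth(self.enface_depth_air_mm, self.n)


def air_to_material_depth(z_air_mm: float, n: float) -> float:
    """Convert a depth measured in air to depth inside the material, z/n."""
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if z_air_mm < 0:
        raise ValueError("depth must be nonnegative")
    return z_air_mm / n


def load_image(
    path, extent_x_mm: float = DEFAULT_EXTENT_MM, extent_y_mm: float | None = None
) -> EnFaceImage:
    """Read a single-channel 8-bit PNG or TIFF en-face image.

    Multi-channel or deeper-than-8-bit rasters are rejected explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise ValueError(
            f"expected single-channel 8-bit image, got shape {arr.shape} "
            f"dtype {arr.dtype}"
        )
    return EnFaceImage(arr, extent_x_mm, extent_y_mm or extent_x_mm)


def save_image(image: EnFaceImage, path) -> None:
    """Write the raster as 8-bit grayscale PNG or TIFF (by suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        from PIL import Image

        Image.fromarray(image.pixels, mode="L").save(path)


def orient_bands(image: EnFaceImage) -> EnFaceImage:
    """Rotate the image so the banding runs parallel to the y-axis.

    Vertical banding makes the column means vary; if instead the row
    means vary more, the image is rotated by 90 degrees.  Ties (e.g. a
    constant image) are left unchanged.
    """
    p = image.pixels.astype(np.float64)
    row_var = float(np.var(p.mean(axis=1)))
    col_var = float(np.var(p.mean(axis=0)))
    if row_var > col_var:
        return EnFaceImage(
            np.rot90(image.pixels, k=-1).copy(), image.extent_y_mm, image.extent_x_mm
        )
    return image


def binarize(image: EnFaceImage, threshold: int = DEFAULT_THRESHOLD) -> BinaryImage:
    """Map pixels strictly above ``threshold`` to 1, the rest to 0."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return BinaryImage((image.pixels > threshold).astype(np.uint8), int(threshold))


_CONN8 = np.ones((3, 3), dtype=int)


def count_grains(binary: BinaryImage) -> int:
    """Number of 8-connected components of value-1 pixels."""
    _, num = ndimage.label(binary.pixels, structure=_CONN8)
    return int(num)


def extract_profile(image: EnFaceImage) -> ReflectivityProfile:
    """Average every image row into the raw reflectivity profile.

    ``rho[j]`` is the mean of column j over all rows; ``x[j]`` is the
    pixel-center abscissa in mm (column pitch = extent / width).
    """
    p = image.pixels.astype(np.float64)
    rho = p.mean(axis=0)
    ncols = p.shape[1]
    pitch = image.extent_x_mm / ncols
    x = (np.arange(ncols) + 0.5) * pitch
    return ReflectivityProfile(x, rho, kind="raw")


def default_smoothing_window(n_points: int) -> int:
    """5% of the profile length, rounded to the nearest odd integer."""
    w = 0.05 * n_points
    k = int(round((w - 1.0) / 2.0))
    return max(1, 2 * k + 1)


def smooth_profile(profile: ReflectivityProfile, window: int | None = None) -> ReflectivityProfile:
    """Centered moving average with a shrinking (truncated) edge window.

    The window must be odd; ``window=1`` is the identity.  The default is
    5% of the profile length (nearest odd).
    """
    if window is None:
        window = default_smoothing_window(profile.x.size)
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    n = profile.rho.size
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(profile.rho)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return ReflectivityProfile(profile.x.copy(), smoothed, kind="smoothed", window=window)


def profile_to_csv(profile: ReflectivityProfile, path) -> None:
    col = "reflectivity" if profile.kind == "raw" else "reflectivity_smoothed"
    pd.DataFrame({"x_mm": profile.x, col: profile.rho}).to_csv(path, index=False)


def profile_from_csv(path) -> ReflectivityProfile:
    df = pd.read_csv(path)
    if "reflectivity" in df.columns:
        return ReflectivityProfile(df["x_mm"].to_numpy(), df["reflectivity"].to_numpy(), "raw")
    if "reflectivity_smoothed" in df.columns:
        return ReflectivityProfile(
            df["x_mm"].to_numpy(), df["reflectivity_smoothed"].to_numpy(), "smoothed"
        )
    raise ValueError(f"{path}: no reflectivity column found")
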