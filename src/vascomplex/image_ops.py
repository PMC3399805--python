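"""Preprocessing of angiographic images into skeletonized binary rasters.

The estimators in this package consume 2-D binary images whose foreground
(value 1) is a 1-pixel-wide vessel skeleton.  This module provides the
standard preprocessing chain for time-of-flight MR angiography:
maximum-intensity projection of the 3-D volume, two-cluster k-means
segmentation of the projected intensities, thinning to a skeleton, and
the left/right hemisphere split used for paired statistics.

Conventions: images are row-major ``(H, W)`` arrays, 0-based, origin at
the top-left; "left hemisphere" means the left half of the image —
mapping display left to anatomical left or right is the caller's concern.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "validate_binary",
    "mip",
    "kmeans_binarize",
    "skeletonize",
    "split_hemispheres",
    "read_image",
    "write_image",
    "read_volume",
]

_AXIS_NAMES = {"axial": 0, "coronal": 1, "sagittal": 2, "0": 0, "1": 1, "2": 2}


def validate_binary(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Coerce to a 2-D uint8 {0,1} array, rejecting anything else."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must contain only 0 and 1")
    return arr.astype(np.uint8)


def mip(volume: np.ndarray, axis: int | str = "axial") -> np.ndarray:
    """Maximum intensity projection of a 3-D volume along one axis.

    Each output pixel is the maximum of all voxels along the projected
    axis; axis 0 ("axial") is the default, matching the axial projection
    of a normalized angiographic volume.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"volume must be 3-D, got shape {vol.shape}")
    if not np.all(np.isfinite(vol)) or np.any(vol < 0):
        raise ValueError("volume intensities must be finite and non-negative")
    if isinstance(axis, str):
        try:
            axis = _AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis label {axis!r}") from None
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return vol.max(axis=axis)


def kmeans_binarize(image: np.ndarray) -> np.ndarray:
    """Segment vessels from background by exact 1-D two-cluster k-means.

    Intensities are clustered into two groups by the threshold that
    minimizes the within-cluster sum of squares, solved exactly on the
    sorted unique values (1-D k-means with k=2 is a threshold rule, so no
    random initialization is involved).  The higher-mean cluster becomes
    the foreground.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("intensities must be finite and non-negative")
    values, counts = np.unique(img, return_counts=True)
    if values.size < 2:
        raise ValueError("no contrast to segment: image is constant")

    # within-cluster sum of squares for every split point, via prefix sums
    w = counts.astype(float)
    s1 = np.cumsum(w * values)
    s2 = np.cumsum(w * values**2)
    n = np.cumsum(w)
    tot1, tot2, totn = s1[-1], s2[-1], n[-1]

    # split after index k: lower cluster = values[:k+1]
    k = np.arange(values.size - 1)
    wcss_lo = s2[k] - s1[k] ** 2 / n[k]
    n_hi = totn - n[k]
    wcss_hi = (tot2 - s2[k]) - (tot1 - s1[k]) ** 2 / n_hi
    best = int(np.argmin(wcss_lo + wcss_hi))
    threshold = values[best]  # foreground: strictly above this value

    return (img > threshold).astype(np.uint8)


def skeletonize(image: np.ndarray) -> np.ndarray:
    """Thin a binary image to 1-pixel-wide curves (Zhang–Suen).

    Connectivity (8-connected components) is preserved; the output
    foreground is a subset of the input foreground.
    """
    img = validate_binary(image)
    if img.sum() == 0:
        return img.copy()
    return _skimage_skeletonize(img.astype(bool), method="zhang").astype(np.uint8)


def split_hemispheres(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an image into left and right halves along the width.

    The canonical in-vivo geometry is a 364x436 raster split into two
    182x436 halves.  The width must be even; pad or crop explicitly
    before calling otherwise.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    h, w = img.shape
    if w % 2 != 0:
        raise ValueError(f"width {w} is odd; pad or crop before splitting")
    return img[:, : w // 2].copy(), img[:, w // 2 :].copy()


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as a 2-D float array (gray) or {0,1} (binary)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) by luminance-free max, vessels are bright
        arr = arr[..., :3].max(axis=-1)
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a raster; binary images are scaled to 0/255 for viewability."""
    path = Path(path)
    arr = np.asarray(image)
    vals = np.unique(arr)
    if np.all(np.isin(vals, (0, 1))):
        arr = (arr * 255).astype(np.uint8)
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI (.nii/.nii.gz) volume as a 3-D float array."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    return vol
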