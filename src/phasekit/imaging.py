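"""Droplet segmentation and fluorescence partition coefficients.

The partition coefficient K = F_droplet / F_background quantifies how
strongly a guest molecule is concentrated inside condensate droplets
relative to the surrounding dilute phase.  F_droplet is the mean intensity
over droplet pixels and F_background a robust (median) background estimate.
K is a ratio statistic: rescaling the image leaves it unchanged.

Edge blur is kept out of both statistics by eroding droplet masks before
averaging and excluding a dilated rim around droplets from the background
sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import dilation, disk, erosion

from .errors import ArgumentError, DataError


@dataclass
class ImageField:
    """A 2D grayscale fluorescence image."""

    pixels: np.ndarray  # (H, W) float intensities
    pixel_size: float = 1.0  # um per px
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ArgumentError("image must be a non-empty 2D grid")
        if (self.pixels < 0).any() or (self.pixels > 2**self.bit_depth - 1).any():
            raise DataError("intensities must lie within the bit depth range")


@dataclass
class SegmentationMask:
    """Labeled droplets (0 = background) with per-droplet area and centroid."""

    labels: np.ndarray  # (H, W) int
    n_droplets: int
    areas_px: list[int]
    centroids: list[tuple[float, float]]


@dataclass
class PartitionResult:
    """K = F_droplet / F_background with a per-droplet breakdown."""

    k_global: float
    k_per_droplet: list[float]
    f_droplet: float
    f_background: float
    n_droplets: int
    background_stat: str = "median"
    droplet_stat: str = "mean"


class NoDropletsError(DataError):
    """Segmentation could not find any droplet (e.g. constant image)."""


def segment_droplets(
    image: ImageField,
    method: str = "otsu",
    min_area_px: int = 20,
    fixed_threshold: float | None = None,
) -> SegmentationMask:
    """Threshold + 8-connected components + small-object removal.

    ``otsu`` picks the global threshold maximizing between-class variance;
    ``fixed`` uses ``fixed_threshold``.  Components smaller than
    ``min_area_px`` are dropped and labels are re-packed densely from 1.
    """
    if method not in ("otsu", "fixed"):
        raise ArgumentError(f"unknown segmentation method: {method!r}")
    px = image.pixels
    if method == "otsu":
        if np.ptp(px) == 0:
            raise NoDropletsError("constant image: Otsu thresholding undefined, no droplets")
        thr = threshold_otsu(px)
    else:
        if fixed_threshold is None:
            raise ArgumentError("fixed_threshold required for method='fixed'")
        thr = float(fixed_threshold)
    binary = px > thr
    lab = sk_label(binary, connectivity=2)
    out = np.zeros_like(lab)
    areas: list[int] = []
    centroids: list[tuple[float, float]] = []
    nxt = 1
    for region in regionprops(lab):
        if region.area < min_area_px:
            continue
        out[lab == region.label] = nxt
        areas.append(int(region.area))
        centroids.append(tuple(region.centroid))
        nxt += 1
    return SegmentationMask(labels=out, n_droplets=nxt - 1, areas_px=areas, centroids=centroids)


def partition_coefficient(
    image: ImageField,
    mask: SegmentationMask,
    erosion_px: int = 2,
    exclusion_px: int = 2,
    background_stat: str = "median",
) -> PartitionResult:
    """K = F_droplet / F_background from an image and a droplet mask.

    F_droplet is the mean over (eroded) droplet pixels; F_background is a
    robust statistic (median by default, mean selectable) over pixels
    outside a dilated exclusion zone around the droplets.
    """
    if mask.n_droplets < 1:
        raise ArgumentError("mask contains no droplets")
    if mask.labels.shape != image.pixels.shape:
        raise ArgumentError("mask shape must match image shape")
    if background_stat not in ("median", "mean"):
        raise ArgumentError(f"unknown background_stat: {background_stat!r}")
    px = image.pixels
    droplet_any = mask.labels > 0
    if exclusion_px > 0:
        excl = dilation(droplet_any, disk(exclusion_px))
    else:
        excl = droplet_any
    bg_pixels = px[~excl]
    if bg_pixels.size == 0:
        raise DataError("background region is empty after exclusion")
    f_bg = float(np.median(bg_pixels) if background_stat == "median" else bg_pixels.mean())
    if f_bg <= 0:
        raise DataError("degenerate background: non-positive background intensity")
    selem = disk(erosion_px) if erosion_px > 0 else None
    droplet_vals = []
    k_per = []
    for label_id in range(1, mask.n_droplets + 1):
        m = mask.labels == label_id
        if selem is not None:
            er = erosion(m, selem)
            if er.any():  # fall back to the raw mask for tiny droplets
                m = er
        vals = px[m]
        droplet_vals.append(vals)
        k_per.append(float(vals.mean() / f_bg))
    all_vals = np.concatenate(droplet_vals)
    f_drop = float(all_vals.mean())
    return PartitionResult(
        k_global=f_drop / f_bg,
        k_per_droplet=k_per,
        f_droplet=f_drop,
        f_background=f_bg,
        n_droplets=mask.n_droplets,
        background_stat=background_stat,
    )


def enhancement_ratio(intensity_sample: float, intensity_reference: float) -> float:
    """Fold enhancement of an emission intensity over a reference medium."""
    if intensity_reference <= 0:
        raise ArgumentError("reference intensity must be positive")
    if intensity_sample < 0:
        raise ArgumentError("sample intensity must be non-negative")
    return intensity_sample / intensity_reference


def load_image(path: str | Path, pixel_size: float = 1.0) -> ImageField:
    """Read a 16-bit grayscale TIFF or PNG into an ImageField."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise DataError(f"{path}: expected a single-channel 2D image")
    return ImageField(pixels=arr.astype(float), pixel_size=pixel_size, bit_depth=16)


def save_image(path: str | Path, image: ImageField) -> None:
    """Write an ImageField as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.round(image.pixels), 0, 2**16 - 1).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)
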