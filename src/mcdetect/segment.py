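"""Thresholding and connected-component extraction of candidates.

The denoised image is thresholded into a binary mask; each maximal
connected foreground region becomes one individual microcalcification
candidate.  Components are labeled deterministically in raster-scan order
of their first-encountered pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .errors import ParameterError
from .image_io import GrayImage

logger = logging.getLogger(__name__)


@dataclass
class BinaryMask:
    """Boolean foreground mask plus the threshold that produced it."""

    pixels: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("mask must be a nonempty 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Component:
    """One connected foreground region (a candidate microcalcification)."""

    label: int
    pixel_count: int
    centroid_px: tuple[float, float]
    bbox_px: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    centroid_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ParameterError("component must contain at least one pixel")
        r0, r1, c0, c1 = self.bbox_px
        r, c = self.centroid_px
        if not (r0 - 0.5 <= r <= r1 - 0.5 and c0 - 0.5 <= c <= c1 - 0.5):
            raise ParameterError("centroid must lie inside the bounding box")


@dataclass
class ComponentSet:
    """All components of one mask, labels contiguous from 1."""

    components: list[Component]
    source_shape: tuple[int, int]
    connectivity: int
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        labels = [c.label for c in self.components]
        if labels != list(range(1, len(labels) + 1)):
            raise ParameterError("labels must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def centroids_px(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids; empty -> shape (0, 2)."""
        if not self.components:
            return np.empty((0, 2))
        return np.array([c.centroid_px for c in self.components])

    def filter_min_size(self, min_size_px: int) -> "ComponentSet":
        """Drop components smaller than ``min_size_px`` pixels, relabeling."""
        kept = [c for c in self.components if c.pixel_count >= min_size_px]
        relabeled = [
            Component(i + 1, c.pixel_count, c.centroid_px, c.bbox_px, c.centroid_mm)
            for i, c in enumerate(kept)
        ]
        return ComponentSet(
            relabeled, self.source_shape, self.connectivity, self.pixel_spacing_mm
        )


def threshold_image(
    image: GrayImage,
    method: str = "quantile",
    t: float | None = None,
    q: float = 0.999,
) -> BinaryMask:
    """Threshold into a binary mask: ``mask = pixels > threshold``.

    Methods
    -------
    ``fixed``
        Use the supplied threshold ``t``.
    ``otsu``
        Maximize between-class variance over the image histogram.  On a
        constant image no foreground is distinguishable; an empty mask is
        returned with a warning.
    ``quantile``
        Threshold at the ``q``-quantile of the pixel values (default
        0.999: candidates are rare bright outliers).
    """
    pixels = image.pixels
    if method == "fixed":
        if t is None or not np.isfinite(t):
            raise ParameterError("fixed thresholding requires a finite t")
        thr = float(t)
    elif method == "otsu":
        if np.ptp(pixels) == 0:
            logger.warning("constant image under Otsu: returning empty mask")
            return BinaryMask(np.zeros(image.shape, dtype=bool), threshold=None)
        thr = float(filters.threshold_otsu(pixels))
    elif method == "quantile":
        if not 0.0 < q < 1.0:
            raise ParameterError(f"quantile q must be in (0, 1), got {q}")
        thr = float(np.quantile(pixels, q))
    else:
        raise ParameterError(f"unknown threshold method '{method}'")
    logger.info("threshold_image: method=%s threshold=%.6g", method, thr)
    return BinaryMask(pixels > thr, threshold=thr)


def extract_components(
    mask: BinaryMask | np.ndarray,
    connectivity: int = 8,
    pixel_spacing_mm: float = 0.05,
) -> ComponentSet:
    """Label maximal connected foreground regions of the mask.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default for blob-like bright spots).  Labels are assigned in
    raster-scan order of each region's first pixel.
    """
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    skimage_conn = 1 if connectivity == 4 else 2
    label_map = measure.label(pixels, connectivity=skimage_conn)
    props = measure.regionprops(label_map)

    # deterministic relabeling by first-encountered pixel in raster order
    def first_pixel_key(p):
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        flat = rows * pixels.shape[1] + cols
        return int(flat.min())

    props = sorted(props, key=first_pixel_key)
    components = []
    for new_label, p in enumerate(props, start=1):
        r0, c0, r1, c1 = p.bbox
        cy, cx = p.centroid
        components.append(
            Component(
                label=new_label,
                pixel_count=int(p.area),
                centroid_px=(float(cy), float(cx)),
                bbox_px=(int(r0), int(r1), int(c0), int(c1)),
                centroid_mm=(float(cy) * pixel_spacing_mm, float(cx) * pixel_spacing_mm),
            )
        )
    return ComponentSet(components, pixels.shape, connectivity, pixel_spacing_mm)
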