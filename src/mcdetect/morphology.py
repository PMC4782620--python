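"""Multi-structuring-element top-hat enhancement of small bright spots.

Microcalcifications are bright structures at most ~1 mm across.  A
grayscale opening with a flat line structuring element (SE) removes every
bright structure that cannot contain the line; subtracting the opening
from the image (the top-hat transform, ``T = f - (f o b)``) therefore
isolates structures smaller than the SE.  Because individual
microcalcifications vary in size and shape, a single SE is not enough: we
probe with a bank of digital lines revolving around a common centre
(default: eight orientations in a 15x15 footprint, i.e. 0.75 mm at
0.05 mm/pixel) and enhance with

    E = f - max_i (f o b_i),

so a structure survives the subtraction (is enhanced) only if *no* line of
the bank fits inside it at its location.  Equivalently, E is the pixelwise
minimum of the individual top-hats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import GrayImage

_VALID_BORDERS = ("reflect", "replicate", "constant", "clip")


@dataclass(frozen=True)
class StructuringElement:
    """A flat (binary) SE with an anchor at the centre of its odd footprint."""

    mask: np.ndarray
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        mask = np.ascontiguousarray(np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2 or any(s % 2 == 0 for s in mask.shape):
            raise ParameterError("SE mask must be 2-D with odd side lengths")
        if not mask.any():
            raise ParameterError("SE mask must contain at least one set pixel")
        ar, ac = self.anchor
        if not mask[ar, ac]:
            raise ParameterError("SE anchor pixel must be set")
        if not np.array_equal(mask, mask[::-1, ::-1]):
            raise ParameterError("SE mask must be point-symmetric about the anchor")

    @property
    def anchor(self) -> tuple[int, int]:
        return (self.mask.shape[0] - 1) // 2, (self.mask.shape[1] - 1) // 2

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def offsets(self) -> np.ndarray:
        """Set-pixel offsets (dr, dc) relative to the anchor, raster order."""
        rr, cc = np.nonzero(self.mask)
        ar, ac = self.anchor
        return np.stack([rr - ar, cc - ac], axis=1)


@dataclass(frozen=True)
class StructuringElementSet:
    """An ordered bank of distinct flat SEs sharing one square footprint."""

    elements: tuple[StructuringElement, ...]
    footprint_px: int

    def __post_init__(self) -> None:
        if not self.elements:
            raise ParameterError("SE set must contain at least one element")
        for se in self.elements:
            if se.mask.shape != (self.footprint_px, self.footprint_px):
                raise ParameterError("all SEs must share the common footprint")
        keys = {se.mask.tobytes() for se in self.elements}
        if len(keys) != len(self.elements):
            raise ParameterError("SEs must be pairwise distinct as pixel sets")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def physical_extent_mm(self, pixel_spacing_mm: float) -> float:
        """Footprint side length in millimetres at the given spacing."""
        return self.footprint_px * pixel_spacing_mm

    def to_json_dict(self) -> dict:
        return {
            "footprint_px": self.footprint_px,
            "elements": [
                {
                    "orientation_deg": se.orientation_deg,
                    "offsets": se.offsets().tolist(),
                }
                for se in self.elements
            ],
        }


def _line_offsets(half: int, theta_deg: float) -> np.ndarray:
    """Symmetric digital line through the origin: each half mirrored.

    The direction vector is scaled so its major component is 1; steps
    s = 0..half then give one pixel per major-axis column/row, i.e. a
    thickness-1 line of exactly 2*half+1 pixels.
    """
    theta = np.deg2rad(theta_deg)
    # image rows grow downwards, so a positive angle tilts the line up
    d = np.array([-np.sin(theta), np.cos(theta)])
    d = d / np.max(np.abs(d))
    steps = np.arange(1, half + 1)
    upper = np.round(steps[:, None] * d[None, :]).astype(int)
    return np.concatenate([-upper[::-1], [[0, 0]], upper], axis=0)


def generate_line_ses(footprint_px: int = 15, n_orientations: int = 8) -> StructuringElementSet:
    """Build the bank of centred digital-line SEs at evenly spaced angles.

    Lines of length ``footprint_px`` are rasterized at angles
    ``k * 180 / n_orientations`` for ``k = 0 .. n_orientations-1``, each
    point-symmetric about the centre of the square footprint.  Orientations
    that rasterize to the same pixel set (possible only for tiny
    footprints) are collapsed, keeping the first.
    """
    if footprint_px < 1 or footprint_px % 2 == 0:
        raise ParameterError(f"footprint_px must be odd and >= 1, got {footprint_px}")
    if n_orientations < 1:
        raise ParameterError("n_orientations must be >= 1")

    half = (footprint_px - 1) // 2
    elements: list[StructuringElement] = []
    seen: set[bytes] = set()
    for k in range(n_orientations):
        angle = 180.0 * k / n_orientations
        mask = np.zeros((footprint_px, footprint_px), dtype=bool)
        offs = _line_offsets(half, angle) if half > 0 else np.array([[0, 0]])
        mask[offs[:, 0] + half, offs[:, 1] + half] = True
        key = mask.tobytes()
        if key in seen:
            continue
        seen.add(key)
        elements.append(StructuringElement(mask, angle))
    return StructuringElementSet(tuple(elements), footprint_px)


def _check_border(border: str, cval: float) -> None:
    if border not in _VALID_BORDERS:
        raise ParameterError(
            f"unknown border policy '{border}'; expected one of {sorted(_VALID_BORDERS)}"
        )


_PAD_MODE = {"reflect": "symmetric", "replicate": "edge"}


def grayscale_opening(
    image: GrayImage, se: StructuringElement, border: str = "reflect", cval: float = 0.0
) -> GrayImage:
    """Flat grayscale opening: erosion followed by dilation with ``se``.

    Extension border policies (``reflect``, ``replicate``, ``constant``)
    extend the *input* once, by the full SE extent, and both passes run on
    that extension before cropping.  (Padding the eroded image again
    instead would break anti-extensivity at borders.)  The ``clip`` policy
    instead restricts each min/max window to the image domain (erosion
    sees +inf outside, dilation -inf); this adjunction convention makes
    the opening exactly idempotent for every SE, whereas reflective
    extension is exactly idempotent only away from the borders for
    oblique SEs.
    """
    _check_border(border, cval)
    if border == "clip":
        eroded = ndimage.grey_erosion(
            image.pixels, footprint=se.mask, mode="constant", cval=np.inf
        )
        opened = ndimage.grey_dilation(
            eroded, footprint=se.mask, mode="constant", cval=-np.inf
        )
        return image.with_pixels(opened)
    h, w = image.shape
    pad_r = se.mask.shape[0] - 1
    pad_c = se.mask.shape[1] - 1
    if border == "constant":
        padded = np.pad(
            image.pixels, ((pad_r, pad_r), (pad_c, pad_c)), constant_values=cval
        )
    else:
        padded = np.pad(
            image.pixels, ((pad_r, pad_r), (pad_c, pad_c)), mode=_PAD_MODE[border]
        )
    eroded = ndimage.grey_erosion(padded, footprint=se.mask, mode="nearest")
    opened = ndimage.grey_dilation(eroded, footprint=se.mask, mode="nearest")
    return image.with_pixels(opened[pad_r : pad_r + h, pad_c : pad_c + w])


def tophat(
    image: GrayImage, se: StructuringElement, border: str = "reflect", cval: float = 0.0
) -> GrayImage:
    """Top-hat transform ``T = f - (f o b)``; nonnegative everywhere."""
    opened = grayscale_opening(image, se, border, cval)
    return image.with_pixels(image.pixels - opened.pixels)


def multi_se_enhance(
    image: GrayImage,
    ses: StructuringElementSet | Sequence[StructuringElement],
    border: str = "reflect",
    cval: float = 0.0,
) -> GrayImage:
    """Multi-SE enhancement ``E = f - max_i (f o b_i)``.

    E is nonnegative and bounded above by every individual top-hat; only
    structures that no SE of the bank fits inside remain.
    """
    elements = list(ses)
    if not elements:
        raise ParameterError("SE set must be nonempty")
    max_open = None
    for se in elements:
        opened = grayscale_opening(image, se, border, cval).pixels
        max_open = opened if max_open is None else np.maximum(max_open, opened)
    return image.with_pixels(image.pixels - max_open)
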