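"""Grayscale image input/output and intensity normalization.

All pipeline stages operate on a float working scale in [0, 1]; integer
images are divided by their dtype maximum on read.  Physical pixel spacing
(mm per pixel side) rides along with the array so that downstream stages
can express block sizes and centroids in millimetres.

Coordinate convention used throughout the package: row-major, 0-based
``(row, col)`` with the origin at the top-left, and half-open bounding
boxes ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterDetection

DEFAULT_PIXEL_SPACING_MM = 0.05

_DETECTION_FIELDS = [
    "block_row", "block_col",
    "r0_px", "r1_px", "c0_px", "c1_px",
    "y0_mm", "y1_mm", "x0_mm", "x1_mm",
    "component_count", "member_labels",
]


@dataclass
class GrayImage:
    """A 2-D grayscale intensity array with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D float array.  After normalization from an integer file the
        values lie in [0, 1]; intermediate pipeline products (e.g. the
        signed output of a wavelet reconstruction) may leave that range
        but must stay finite.
    pixel_spacing_mm
        Physical side length of one pixel in millimetres (default 0.05,
        typical of full-resolution digitized mammograms).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError(
                f"GrayImage requires a 2-D array, got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise ParameterError("GrayImage requires a nonempty array")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("GrayImage intensities must be finite")
        if not self.pixel_spacing_mm > 0:
            raise ParameterError("pixel_spacing_mm must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """New image with the same spacing and different pixel data."""
        return GrayImage(pixels, self.pixel_spacing_mm)


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Map an integer array onto [0, 1] by its dtype maximum (monotone)."""
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return raw.astype(np.float64) / float(info.max)
    out = raw.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise FormatError("float image contains non-finite values")
    return out


def read_image(path: str | Path, spacing_override: float | None = None) -> GrayImage:
    """Read a single-channel 8/16-bit TIFF or PNG, or a monochrome DICOM.

    Integer intensities are divided by their dtype maximum into [0, 1].
    Pixel spacing is taken from the DICOM PixelSpacing tag when present,
    else from ``spacing_override``, else the 0.05 mm default.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if spacing_override is not None and not spacing_override > 0:
        raise ParameterError("spacing_override must be positive")

    suffix = path.suffix.lower()
    spacing = spacing_override
    if suffix in {".dcm", ".dicom"}:
        raw, dicom_spacing = _read_dicom(path)
        if dicom_spacing is not None:
            spacing = dicom_spacing
    elif suffix in {".tif", ".tiff"}:
        import tifffile

        raw = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        raw = iio.imread(path)
    else:
        raise FormatError(f"unsupported image format: '{suffix}'")

    raw = np.asarray(raw)
    if raw.ndim == 3:
        raise FormatError(
            f"expected single-channel image, got {raw.shape[-1]} channels"
        )
    if raw.ndim != 2:
        raise FormatError(f"expected 2-D image, got ndim={raw.ndim}")
    return GrayImage(_normalize(raw), spacing if spacing is not None else DEFAULT_PIXEL_SPACING_MM)


def _read_dicom(path: Path) -> tuple[np.ndarray, float | None]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError(
            "DICOM input requires the optional 'pydicom' dependency"
        ) from exc
    ds = pydicom.dcmread(path)
    raw = ds.pixel_array
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    samples = int(getattr(ds, "SamplesPerPixel", 1))
    if samples != 1:
        raise FormatError(f"expected monochrome DICOM, got {samples} samples/pixel")
    return raw, spacing


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a [0, 1]-scaled image back to a 16-bit TIFF or 8-bit PNG."""
    path = Path(path)
    clipped = np.clip(image.pixels, 0.0, 1.0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, np.round(clipped * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, np.round(clipped * 255).astype(np.uint8))
    else:
        raise FormatError(f"unsupported output format: '{path.suffix}'")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def _detection_record(det: "ClusterDetection") -> dict:
    (r0, r1), (c0, c1) = det.bbox_px[:2], det.bbox_px[2:]
    (y0, y1), (x0, x1) = det.bbox_mm[:2], det.bbox_mm[2:]
    return {
        "block_row": det.block_index[0],
        "block_col": det.block_index[1],
        "r0_px": r0, "r1_px": r1, "c0_px": c0, "c1_px": c1,
        "y0_mm": y0, "y1_mm": y1, "x0_mm": x0, "x1_mm": x1,
        "component_count": det.component_count,
        "member_labels": list(det.member_labels),
    }


def write_detections(
    detections: Sequence["ClusterDetection"],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write cluster detections to CSV (header always present) or JSON.

    The format is inferred from the file suffix when not given.  Records
    round-trip losslessly through :func:`read_detections`.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    records = [_detection_record(d) for d in detections]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_DETECTION_FIELDS)
            writer.writeheader()
            for rec in records:
                rec = dict(rec)
                rec["member_labels"] = ";".join(str(l) for l in rec["member_labels"])
                writer.writerow(rec)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
            fh.write("\n")
    else:
        raise ParameterError(f"unknown detections format: '{fmt}'")


def read_detections(path: str | Path, format: str | None = None) -> list["ClusterDetection"]:
    """Read detections previously written by :func:`write_detections`."""
    from .cluster import ClusterDetection

    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, newline="") as fh:
            rows: Iterable[dict] = list(csv.DictReader(fh))
        records = []
        for row in rows:
            rec = {k: row[k] for k in _DETECTION_FIELDS}
            rec["member_labels"] = [
                int(tok) for tok in row["member_labels"].split(";") if tok
            ]
            records.append(rec)
    elif fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        raise ParameterError(f"unknown detections format: '{fmt}'")

    out = []
    for rec in records:
        out.append(
            ClusterDetection(
                block_index=(int(rec["block_row"]), int(rec["block_col"])),
                bbox_px=(
                    int(rec["r0_px"]), int(rec["r1_px"]),
                    int(rec["c0_px"]), int(rec["c1_px"]),
                ),
                bbox_mm=(
                    float(rec["y0_mm"]), float(rec["y1_mm"]),
                    float(rec["x0_mm"]), float(rec["x1_mm"]),
                ),
                member_labels=tuple(int(l) for l in rec["member_labels"]),
            )
        )
    return out
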