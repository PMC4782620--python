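"""Seeded synthetic mammogram-like phantoms with ground truth.

No public dataset exists for the kind of full-resolution clinical
mammograms this detector targets, so the package ships a generator that
emulates the structures the method cares about:

* small bright quasi-Gaussian spots 0.05--1 mm across, grouped four or
  more to a cluster within a compact (few-mm) neighbourhood — stand-ins
  for individual microcalcifications;
* curvilinear bright ridges one to two pixels wide with nonhomogeneous
  intensity — stand-ins for the mammary glands and vessels that the
  top-hat stage also enhances and the wavelet stage must suppress;
* a smooth low-contrast background and additive Gaussian noise.

Every random layer (background / spots / lines / noise) draws from its
own named stream derived from the master seed, so one layer can be varied
without perturbing the others.  Images are float in [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .errors import SpecError, ParameterError
from .image_io import GrayImage

DEFAULT_IMAGE_PX = (1024, 1024)
DEFAULT_SPACING_MM = 0.05


@dataclass(frozen=True)
class BackgroundSpec:
    """Smooth low-frequency background field.

    ``amplitude`` is the maximum deviation from ``base`` (the random
    low-pass field is rescaled to unit peak), so pixel values stay inside
    [base - amplitude, base + amplitude].
    """

    base: float = 0.35
    amplitude: float = 0.08
    scale_px: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base <= 1.0 or not 0.0 <= self.amplitude <= 1.0:
            raise SpecError("background base and amplitude must lie in [0, 1]")
        if self.base + self.amplitude > 1.0 or self.base - self.amplitude < 0.0:
            raise SpecError("background band must stay inside [0, 1]")


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster of bright spots.

    ``extent_mm`` bounds the area a cluster may occupy (the operational
    definition uses 10 mm); realized spot centres are drawn uniformly from
    a disc of radius ``spread_mm`` (default extent/4, i.e. a compact 5-mm
    cluster) centred at ``center_mm``.  Spot diameter is the full truncated
    footprint of the Gaussian profile (cut at 3 sigma), so
    ``sigma = diameter / 6``.
    """

    center_mm: tuple[float, float]  # (y, x)
    extent_mm: float = 10.0
    n_spots: int | None = None  # None -> draw uniformly in [4, 10]
    spot_diameter_mm: tuple[float, float] = (0.3, 0.6)
    spot_amplitude: tuple[float, float] = (0.2, 0.35)
    spread_mm: float | None = None  # None -> extent_mm / 4
    square_spots: bool = False  # exact-arithmetic test aid

    def __post_init__(self) -> None:
        lo, hi = self.spot_diameter_mm
        if not 0.0 < lo <= hi:
            raise SpecError("spot_diameter_mm must be an increasing positive range")
        alo, ahi = self.spot_amplitude
        if not 0.0 <= alo <= ahi <= 1.0:
            raise SpecError("spot_amplitude must be a range within [0, 1]")
        if self.n_spots is not None and self.n_spots < 1:
            raise SpecError("n_spots must be >= 1")

    @property
    def effective_spread_mm(self) -> float:
        return self.spread_mm if self.spread_mm is not None else self.extent_mm / 4.0


@dataclass(frozen=True)
class LineSpec:
    """A curvilinear bright ridge (gland/vessel confounder).

    ``control_points_mm`` are (y, x) way-points of a smooth curve;
    ``width_px`` is the Gaussian cross-section scale (kept below the SE
    footprint so the top-hat passes the ridge and the wavelet stage must
    suppress it); ``jitter`` is the fractional per-pixel multiplicative
    intensity variation realizing nonhomogeneous tissue intensity.
    """

    control_points_mm: tuple[tuple[float, float], ...]
    width_px: float = 1.2
    amplitude: float = 0.18
    jitter: float = 0.3

    def __post_init__(self) -> None:
        if len(self.control_points_mm) < 2:
            raise SpecError("a line needs at least two control points")
        if not 0.0 <= self.amplitude <= 1.0:
            raise SpecError("line amplitude must lie in [0, 1]")
        if not self.width_px > 0:
            raise SpecError("line width must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic image."""

    image_px: tuple[int, int] = DEFAULT_IMAGE_PX
    pixel_spacing_mm: float = DEFAULT_SPACING_MM
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    clusters: tuple[ClusterSpec, ...] = ()
    lines: tuple[LineSpec, ...] = ()
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_px
        if min(h, w) < 16:
            raise SpecError("image sides must be >= 16 (decomposable at 4 levels)")
        if not self.pixel_spacing_mm > 0:
            raise SpecError("pixel_spacing_mm must be positive")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be nonnegative")


@dataclass
class GroundTruth:
    """Realized structures of one phantom."""

    spot_centers_px: list[np.ndarray]  # one (n_i, 2) array per cluster
    cluster_boxes_px: list[tuple[int, int, int, int]]  # half-open boxes
    line_mask: np.ndarray  # union of confounder ridge supports

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_boxes_px)


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    bg = spec.background
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(spec.image_px), bg.scale_px, mode="reflect"
    )
    peak = np.max(np.abs(field_))
    if peak > 0:
        field_ = field_ / peak
    return bg.base + bg.amplitude * field_


def _stamp_spot(
    canvas: np.ndarray,
    center: tuple[float, float],
    diameter_px: float,
    amplitude: float,
    square: bool,
) -> None:
    cy, cx = center
    radius = diameter_px / 2.0
    r0 = max(0, int(math.floor(cy - radius)) - 1)
    r1 = min(canvas.shape[0], int(math.ceil(cy + radius)) + 2)
    c0 = max(0, int(math.floor(cx - radius)) - 1)
    c1 = min(canvas.shape[1], int(math.ceil(cx + radius)) + 2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    if square:
        patch = np.where(
            (np.abs(rr - cy) <= radius) & (np.abs(cc - cx) <= radius), amplitude, 0.0
        )
    else:
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        sigma = diameter_px / 6.0  # profile truncated at 3 sigma
        patch = amplitude * np.exp(-d2 / (2.0 * sigma**2))
        patch[d2 > (3.0 * sigma) ** 2] = 0.0
    np.maximum(canvas[r0:r1, c0:c1], patch, out=canvas[r0:r1, c0:c1])


def _render_cluster(
    spec: PhantomSpec,
    cspec: ClusterSpec,
    idx: int,
    canvas: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    sp = spec.pixel_spacing_mm
    cy, cx = cspec.center_mm[0] / sp, cspec.center_mm[1] / sp
    spread_px = cspec.effective_spread_mm / sp
    n = cspec.n_spots if cspec.n_spots is not None else int(rng.integers(4, 11))

    centers = np.empty((n, 2))
    for i in range(n):
        # uniform in a disc of radius spread_px
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = spread_px * math.sqrt(rng.uniform())
        centers[i] = (cy + rad * math.sin(ang), cx + rad * math.cos(ang))

    diam_lo, diam_hi = cspec.spot_diameter_mm
    amp_lo, amp_hi = cspec.spot_amplitude
    max_radius_px = 0.0
    for i in range(n):
        diam_px = rng.uniform(diam_lo, diam_hi) / sp
        amp = rng.uniform(amp_lo, amp_hi)
        y, x = centers[i]
        if not (0 <= y < spec.image_px[0] and 0 <= x < spec.image_px[1]):
            raise SpecError(
                f"cluster {idx}: spot at px ({y:.1f}, {x:.1f}) falls outside "
                f"the {spec.image_px} image"
            )
        _stamp_spot(canvas, (y, x), diam_px, amp, cspec.square_spots)
        max_radius_px = max(max_radius_px, diam_px / 2.0)

    pad = max_radius_px + 2.0
    box = (
        max(0, int(math.floor(centers[:, 0].min() - pad))),
        min(spec.image_px[0], int(math.ceil(centers[:, 0].max() + pad)) + 1),
        max(0, int(math.floor(centers[:, 1].min() - pad))),
        min(spec.image_px[1], int(math.ceil(centers[:, 1].max() + pad)) + 1),
    )
    return centers, box


def _render_line(
    spec: PhantomSpec,
    lspec: LineSpec,
    canvas: np.ndarray,
    truth_mask: np.ndarray,
    rng: np.random.Generator,
) -> None:
    sp = spec.pixel_spacing_mm
    pts = np.asarray(lspec.control_points_mm, dtype=float) / sp
    # chord-length parametrization; cubic through the way-points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        raise SpecError("line control points are all coincident")
    if len(pts) == 2:
        n_dense = max(int(t[-1] * 4), 2)
        dense = np.linspace(0, 1, n_dense)[:, None] * (pts[1] - pts[0]) + pts[0]
    else:
        cs = CubicSpline(t, pts, axis=0)
        dense = cs(np.linspace(0.0, t[-1], max(int(t[-1] * 4), 2)))

    centerline = np.zeros(spec.image_px, dtype=bool)
    idx = np.round(dense).astype(int)
    ok = (
        (idx[:, 0] >= 0)
        & (idx[:, 0] < spec.image_px[0])
        & (idx[:, 1] >= 0)
        & (idx[:, 1] < spec.image_px[1])
    )
    idx = idx[ok]
    if len(idx) == 0:
        return
    centerline[idx[:, 0], idx[:, 1]] = True

    dist = ndimage.distance_transform_edt(~centerline)
    sigma = lspec.width_px / 2.0
    profile = lspec.amplitude * np.exp(-(dist**2) / (2.0 * sigma**2))
    profile[dist > 3.0 * sigma] = 0.0
    if lspec.jitter > 0:
        # multiplicative variation correlated at the ridge-width (gland)
        # scale, so the nonhomogeneity itself stays sub-microcalcification
        mod = ndimage.gaussian_filter(
            rng.uniform(-1.0, 1.0, spec.image_px), lspec.width_px
        )
        peak = np.max(np.abs(mod))
        if peak > 0:
            mod = mod / peak
        profile = profile * (1.0 + lspec.jitter * mod)
    np.maximum(canvas, profile, out=canvas)
    truth_mask |= dist <= max(lspec.width_px, 1.0)


def generate(spec: PhantomSpec) -> tuple[GrayImage, GroundTruth]:
    """Realize a phantom: ``clip(background + spots + ridges + noise, 0, 1)``.

    Deterministic for a fixed spec (the seed is part of the spec); the
    returned ground truth records every realized spot centre, one padded
    bounding box per cluster, and the ridge support mask.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_bg, rng_spots, rng_lines, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    image = _background(spec, rng_bg)

    spots = np.zeros(spec.image_px)
    spot_centers: list[np.ndarray] = []
    cluster_boxes: list[tuple[int, int, int, int]] = []
    for i, cspec in enumerate(spec.clusters):
        centers, box = _render_cluster(spec, cspec, i, spots, rng_spots)
        spot_centers.append(centers)
        cluster_boxes.append(box)

    ridges = np.zeros(spec.image_px)
    line_mask = np.zeros(spec.image_px, dtype=bool)
    for lspec in spec.lines:
        _render_line(spec, lspec, ridges, line_mask, rng_lines)

    image = image + spots + ridges
    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sigma, spec.image_px)
    image = np.clip(image, 0.0, 1.0)
    return (
        GrayImage(image, spec.pixel_spacing_mm),
        GroundTruth(spot_centers, cluster_boxes, line_mask),
    )


def _random_lines(
    spec_shape: tuple[int, int],
    spacing: float,
    n_lines: int,
    rng: np.random.Generator,
) -> tuple[LineSpec, ...]:
    """Random smooth curves spanning a good fraction of the frame."""
    h_mm = spec_shape[0] * spacing
    w_mm = spec_shape[1] * spacing
    lines = []
    for _ in range(n_lines):
        start = np.array([rng.uniform(0, h_mm), rng.uniform(0, w_mm)])
        ang = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.sin(ang), math.cos(ang)])
        length = rng.uniform(0.5, 1.0) * min(h_mm, w_mm)
        n_ctrl = int(rng.integers(3, 6))
        ts = np.linspace(0.0, 1.0, n_ctrl)
        lateral = rng.normal(0.0, 0.06 * length, n_ctrl)
        normal = np.array([-direction[1], direction[0]])
        pts = start[None, :] + ts[:, None] * length * direction[None, :]
        pts = pts + lateral[:, None] * normal[None, :]
        lines.append(
            LineSpec(
                control_points_mm=tuple(map(tuple, pts)),
                width_px=float(rng.uniform(1.0, 2.0)),
                amplitude=float(rng.uniform(0.12, 0.22)),
                jitter=0.3,
            )
        )
    return tuple(lines)


def default_benchmark_suite(
    n_images: int,
    seed: int,
    image_px: tuple[int, int] = DEFAULT_IMAGE_PX,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
    positive_fraction: float = 0.1,
) -> list[tuple[GrayImage, GroundTruth]]:
    """A reproducible mixed suite mirroring a screening population.

    About ``positive_fraction`` of the images (10% by default, at least
    one) contain one or two clusters; every image contains two to six
    curvilinear gland-like confounders.  Per-image seeds are derived from
    the master seed, so the suite is reproducible as a whole.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence(seed))
    n_pos = max(1, round(positive_fraction * n_images)) if positive_fraction > 0 else 0
    pos_idx = set(
        master.choice(n_images, size=min(n_pos, n_images), replace=False).tolist()
    )
    h_mm = image_px[0] * pixel_spacing_mm
    w_mm = image_px[1] * pixel_spacing_mm

    suite = []
    for i in range(n_images):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        clusters: list[ClusterSpec] = []
        if i in pos_idx:
            n_clusters = int(rng.integers(1, 3))
            # keep the full cluster extent inside the frame; shrink the
            # margin (and separation) for frames smaller than two extents
            margin = min(10.0, min(h_mm, w_mm) / 2.0 - 3.0)
            if margin <= 0:
                raise ParameterError("image too small to place a cluster")
            separation = min(10.0, min(h_mm, w_mm) - 2.0 * margin)
            centers: list[np.ndarray] = []
            attempts = 0
            while len(centers) < n_clusters:
                cand = np.array(
                    [rng.uniform(margin, h_mm - margin), rng.uniform(margin, w_mm - margin)]
                )
                attempts += 1
                if attempts > 200 or all(
                    np.linalg.norm(cand - c) >= separation for c in centers
                ):
                    centers.append(cand)
            clusters = [ClusterSpec(center_mm=tuple(c)) for c in centers]
        lines = _random_lines(image_px, pixel_spacing_mm, int(rng.integers(2, 7)), rng)
        spec = PhantomSpec(
            image_px=image_px,
            pixel_spacing_mm=pixel_spacing_mm,
            clusters=tuple(clusters),
            lines=lines,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suite.append(generate(spec))
    return suite


def spec_to_json(spec: PhantomSpec) -> str:
    """Serialize a phantom spec to JSON (echoed next to written phantoms)."""
    return json.dumps(asdict(spec), indent=2)


def truth_to_json_dict(truth: GroundTruth) -> dict:
    return {
        "spot_centers_px": [c.tolist() for c in truth.spot_centers_px],
        "cluster_boxes_px": [list(b) for b in truth.cluster_boxes_px],
    }
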