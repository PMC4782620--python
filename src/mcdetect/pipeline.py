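"""End-to-end detector: enhance -> denoise -> segment -> cluster.

The default configuration encodes the published operating point of the
method: an 8-orientation line-SE bank in a 15x15 footprint (0.75 mm at
0.05 mm/pixel), a 4-level symlet-2 decomposition zeroing the finest
detail triplet and the approximation, quantile thresholding of the
band-pass result, and the 10x10 mm^2 / >= 4 components block rule on a
half-overlapping grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import yaml

from . import cluster as cluster_mod
from . import morphology, segment, wavelet
from .errors import ParameterError, StageError
from .image_io import GrayImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SEConfig:
    footprint_px: int = 15
    n_orientations: int = 8
    border: str = "reflect"


@dataclass(frozen=True)
class WaveletConfig:
    name: str = "sym2"
    levels: int = 4
    mode: str = "symmetric"
    zero_approx: bool = True
    zero_finest_detail: bool = True


@dataclass(frozen=True)
class SegmentConfig:
    method: str = "quantile"
    q: float = 0.999
    t: float | None = None
    # a per-image quantile always marks some foreground, so cluster-free
    # images would hallucinate candidates; responses below this absolute
    # band-pass contrast are treated as tissue/noise residue
    min_threshold: float = 0.13
    connectivity: int = 8
    # ridge residues fragment into 1-2 px shards; real spot responses
    # at the retained scales cover more pixels
    min_size_px: int = 3


@dataclass(frozen=True)
class ClusterConfig:
    block_mm: float = 10.0
    step_fraction: float = 0.5
    min_count: int = 4


@dataclass(frozen=True)
class IOConfig:
    pixel_spacing_mm: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults are the published configuration."""

    se: SEConfig = field(default_factory=SEConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0

    def block_px(self, pixel_spacing_mm: float) -> int:
        """Block side in pixels preserving the physical block_mm rule."""
        return max(1, round(self.cluster.block_mm / pixel_spacing_mm))

    def step_px(self, pixel_spacing_mm: float) -> int:
        return max(1, round(self.block_px(pixel_spacing_mm) * self.cluster.step_fraction))

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        return PipelineConfig(
            se=SEConfig(**d.get("se", {})),
            wavelet=WaveletConfig(**d.get("wavelet", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            cluster=ClusterConfig(**d.get("cluster", {})),
            io=IOConfig(**d.get("io", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return PipelineConfig.from_dict(data)


def run_pipeline(
    image: GrayImage,
    config: PipelineConfig | None = None,
    keep_intermediate: bool = False,
) -> tuple[list[cluster_mod.ClusterDetection], dict]:
    """Run the full detector on one image.

    Returns the merged cluster detections and a dict of stage artifacts
    (always the component set and grid; the enhanced, denoised and mask
    images too when ``keep_intermediate`` is set).  Deterministic for a
    fixed image and config.
    """
    if config is None:
        config = PipelineConfig()
    spacing = image.pixel_spacing_mm
    logger.info(
        "pipeline: SE %dx%d px (%.2f mm) x %d orientations; wavelet %s x%d; "
        "threshold %s; block %d px (%.1f mm) step %d px; min_count %d",
        config.se.footprint_px, config.se.footprint_px,
        config.se.footprint_px * spacing, config.se.n_orientations,
        config.wavelet.name, config.wavelet.levels, config.segment.method,
        config.block_px(spacing), config.cluster.block_mm,
        config.step_px(spacing), config.cluster.min_count,
    )

    artifacts: dict = {}
    try:
        ses = morphology.generate_line_ses(
            config.se.footprint_px, config.se.n_orientations
        )
        enhanced = morphology.multi_se_enhance(image, ses, border=config.se.border)
    except Exception as exc:
        raise StageError("enhance", exc) from exc
    if keep_intermediate:
        artifacts["enhanced"] = enhanced

    try:
        zero_levels = {config.wavelet.levels} if config.wavelet.zero_finest_detail else set()
        sel = wavelet.SubbandSelector(
            zero_approx=config.wavelet.zero_approx,
            zero_detail_levels=frozenset(zero_levels),
        )
        denoised = wavelet.denoise(
            enhanced, sel, config.wavelet.name, config.wavelet.levels,
            config.wavelet.mode,
        )
    except Exception as exc:
        raise StageError("denoise", exc) from exc
    if keep_intermediate:
        artifacts["denoised"] = denoised

    try:
        mask = segment.threshold_image(
            denoised, method=config.segment.method, t=config.segment.t,
            q=config.segment.q,
        )
        if (
            config.segment.method == "quantile"
            and mask.threshold is not None
            and mask.threshold < config.segment.min_threshold
        ):
            logger.info(
                "quantile threshold %.4g below contrast floor %.4g; using floor",
                mask.threshold, config.segment.min_threshold,
            )
            mask = segment.BinaryMask(
                denoised.pixels > config.segment.min_threshold,
                threshold=config.segment.min_threshold,
            )
        comps = segment.extract_components(
            mask, config.segment.connectivity, spacing
        )
        if config.segment.min_size_px > 0:
            comps = comps.filter_min_size(config.segment.min_size_px)
    except Exception as exc:
        raise StageError("segment", exc) from exc
    if keep_intermediate:
        artifacts["mask"] = mask
    artifacts["components"] = comps

    try:
        block_px = min(config.block_px(spacing), min(image.shape))
        step_px = min(config.step_px(spacing), block_px)
        grid = cluster_mod.make_grid(image.shape, block_px, step_px)
        raw = cluster_mod.detect_clusters(comps, grid, config.cluster.min_count)
        merged = cluster_mod.merge_detections(raw)
    except Exception as exc:
        raise StageError("cluster", exc) from exc
    artifacts["grid"] = grid
    artifacts["raw_detections"] = raw
    return merged, artifacts
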