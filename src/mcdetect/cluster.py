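"""Block-based cluster labeling.

A microcalcification cluster is, operationally, four or more individual
microcalcifications within a limited area of about 10 x 10 mm^2.  The
candidate mask is tiled into square blocks (default 200 px = 10 mm at
0.05 mm/pixel) that overlap their neighbours by half a block in each
axis; any block whose component count reaches ``min_count`` (default 4,
i.e. "more than three") is labeled a cluster.  Overlapping block hits
that share candidate components are merged into one detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .segment import ComponentSet

DEFAULT_BLOCK_PX = 200
DEFAULT_STEP_PX = 100
DEFAULT_MIN_COUNT = 4


def _axis_anchors(extent: int, block: int, step: int) -> list[int]:
    """Anchors 0, step, 2*step, ..., with the last clamped so the final
    block abuts the image edge; every pixel is covered."""
    anchors = list(range(0, extent - block + 1, step))
    if anchors[-1] != extent - block:
        anchors.append(extent - block)
    return anchors


@dataclass(frozen=True)
class BlockGrid:
    """Overlapping square tiling of an image."""

    image_shape: tuple[int, int]
    block_px: int = DEFAULT_BLOCK_PX
    step_px: int = DEFAULT_STEP_PX

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if self.block_px < 1 or self.step_px < 1:
            raise ParameterError("block_px and step_px must be positive")
        if self.step_px > self.block_px:
            raise ParameterError("step_px must not exceed block_px")
        if self.block_px > min(h, w):
            raise ParameterError(
                f"block ({self.block_px} px) larger than image {self.image_shape}"
            )

    @property
    def row_anchors(self) -> list[int]:
        return _axis_anchors(self.image_shape[0], self.block_px, self.step_px)

    @property
    def col_anchors(self) -> list[int]:
        return _axis_anchors(self.image_shape[1], self.block_px, self.step_px)

    @property
    def n_blocks(self) -> int:
        return len(self.row_anchors) * len(self.col_anchors)

    def block_box(self, row_i: int, col_i: int) -> tuple[int, int, int, int]:
        """Half-open (r0, r1, c0, c1) of block (row_i, col_i)."""
        r0 = self.row_anchors[row_i]
        c0 = self.col_anchors[col_i]
        return r0, r0 + self.block_px, c0, c0 + self.block_px


@dataclass(frozen=True)
class ClusterDetection:
    """A detected microcalcification cluster.

    ``bbox_px`` is half-open in pixels; ``bbox_mm`` is the same box in
    millimetres (y0, y1, x0, x1).  ``member_labels`` are the component
    labels counted inside the block (or the union after merging).
    """

    block_index: tuple[int, int]
    bbox_px: tuple[int, int, int, int]
    bbox_mm: tuple[float, float, float, float]
    member_labels: tuple[int, ...]

    @property
    def component_count(self) -> int:
        return len(self.member_labels)

    def center_px(self) -> tuple[float, float]:
        r0, r1, c0, c1 = self.bbox_px
        return (r0 + r1) / 2.0, (c0 + c1) / 2.0


def make_grid(
    image_shape: tuple[int, int],
    block_px: int = DEFAULT_BLOCK_PX,
    step_px: int = DEFAULT_STEP_PX,
) -> BlockGrid:
    """Construct the overlapping block grid for an image shape."""
    return BlockGrid(tuple(image_shape), block_px, step_px)


def detect_clusters(
    components: ComponentSet,
    grid: BlockGrid,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[ClusterDetection]:
    """Emit every block containing at least ``min_count`` components.

    A component belongs to a block iff its centroid lies inside the
    block's half-open box; a component near an overlap region may belong
    to several blocks, producing duplicate hits that
    :func:`merge_detections` consolidates.
    """
    if components.source_shape != grid.image_shape:
        raise ParameterError(
            f"components shape {components.source_shape} != grid shape {grid.image_shape}"
        )
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    spacing = components.pixel_spacing_mm
    centroids = components.centroids_px()
    labels = np.array([c.label for c in components.components], dtype=int)
    detections: list[ClusterDetection] = []
    for row_i in range(len(grid.row_anchors)):
        for col_i in range(len(grid.col_anchors)):
            r0, r1, c0, c1 = grid.block_box(row_i, col_i)
            if len(centroids):
                inside = (
                    (centroids[:, 0] >= r0)
                    & (centroids[:, 0] < r1)
                    & (centroids[:, 1] >= c0)
                    & (centroids[:, 1] < c1)
                )
                members = labels[inside]
            else:
                members = labels[:0]
            if len(members) >= min_count:
                detections.append(
                    ClusterDetection(
                        block_index=(row_i, col_i),
                        bbox_px=(r0, r1, c0, c1),
                        bbox_mm=(
                            r0 * spacing, r1 * spacing, c0 * spacing, c1 * spacing
                        ),
                        member_labels=tuple(int(l) for l in members),
                    )
                )
    return detections


def merge_detections(raw: list[ClusterDetection]) -> list[ClusterDetection]:
    """Merge block detections that share at least one member component.

    Merging is transitive (connected groups in the block-sharing graph);
    the merged detection unions member sets and bounding boxes, and keeps
    the smallest block index of its group.  Idempotent.
    """
    n = len(raw)
    if n <= 1:
        return list(raw)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    label_to_first: dict[int, int] = {}
    for i, det in enumerate(raw):
        for lab in det.member_labels:
            if lab in label_to_first:
                union(label_to_first[lab], i)
            else:
                label_to_first[lab] = i

    groups: dict[int, list[ClusterDetection]] = {}
    for i, det in enumerate(raw):
        groups.setdefault(find(i), []).append(det)

    merged: list[ClusterDetection] = []
    for dets in groups.values():
        members = sorted({lab for d in dets for lab in d.member_labels})
        bbox_px = (
            min(d.bbox_px[0] for d in dets),
            max(d.bbox_px[1] for d in dets),
            min(d.bbox_px[2] for d in dets),
            max(d.bbox_px[3] for d in dets),
        )
        bbox_mm = (
            min(d.bbox_mm[0] for d in dets),
            max(d.bbox_mm[1] for d in dets),
            min(d.bbox_mm[2] for d in dets),
            max(d.bbox_mm[3] for d in dets),
        )
        block_index = min(d.block_index for d in dets)
        merged.append(
            ClusterDetection(block_index, bbox_px, bbox_mm, tuple(members))
        )
    merged.sort(key=lambda d: d.block_index)
    return merged
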