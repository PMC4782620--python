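"""Cluster-level scoring: true-positive rate and false positives per image.

The standard operating-point metrics for mammographic CAD: the fraction
of true clusters detected (TPR, percent) and the number of spurious
cluster detections divided by the number of images (FP/image).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cluster import ClusterDetection
from .errors import ParameterError

Box = tuple[float, float, float, float]  # half-open (r0, r1, c0, c1)


@dataclass
class EvalResult:
    """Tallies of a cluster-level evaluation over a set of images."""

    n_true_clusters: int
    n_detected_true: int
    n_false_detections: int
    n_images: int
    per_image_records: list[dict] = field(default_factory=list)

    @property
    def tpr_percent(self) -> float | None:
        """Percent of true clusters detected; None when no truth exists."""
        if self.n_true_clusters == 0:
            return None
        return 100.0 * self.n_detected_true / self.n_true_clusters

    @property
    def fp_per_image(self) -> float:
        return self.n_false_detections / self.n_images

    def summary(self) -> str:
        tpr = self.tpr_percent
        tpr_str = "undefined (no true clusters)" if tpr is None else f"{tpr:.1f}%"
        return (
            f"images: {self.n_images}\n"
            f"true clusters: {self.n_true_clusters}\n"
            f"detected true clusters: {self.n_detected_true}\n"
            f"TPR: {tpr_str}\n"
            f"false detections: {self.n_false_detections}\n"
            f"FP/image: {self.fp_per_image:.2f}"
        )


def _box_center(box: Box) -> tuple[float, float]:
    r0, r1, c0, c1 = box
    return (r0 + r1) / 2.0, (c0 + c1) / 2.0


def _center_in(box: Box, point: tuple[float, float]) -> bool:
    r0, r1, c0, c1 = box
    return r0 <= point[0] < r1 and c0 <= point[1] < c1


def _overlap_area(a: Box, b: Box) -> float:
    dr = min(a[1], b[1]) - max(a[0], b[0])
    dc = min(a[3], b[3]) - max(a[2], b[2])
    return max(dr, 0.0) * max(dc, 0.0)


def _iou(a: Box, b: Box) -> float:
    inter = _overlap_area(a, b)
    if inter == 0.0:
        return 0.0
    area_a = (a[1] - a[0]) * (a[3] - a[2])
    area_b = (b[1] - b[0]) * (b[3] - b[2])
    return inter / (area_a + area_b - inter)


def _matches(det_box: Box, truth_box: Box, rule: str, min_iou: float) -> bool:
    if rule == "center_in_box":
        return _center_in(det_box, _box_center(truth_box)) or _center_in(
            truth_box, _box_center(det_box)
        )
    if rule == "box_overlap":
        return _iou(det_box, truth_box) >= min_iou
    raise ParameterError(f"unknown match rule '{rule}'")


def match_and_score(
    detections_per_image: Sequence[Sequence[ClusterDetection]],
    truths_per_image: Sequence[Sequence[Box]],
    match_rule: str = "center_in_box",
    min_iou: float = 0.2,
) -> EvalResult:
    """Greedily match detections to true cluster boxes and tally metrics.

    A true cluster counts as detected when at least one detection matches
    it; each true cluster can be claimed by at most one detection (greedy
    by descending overlap area) but one detection may cover several true
    clusters.  Detections matching no truth are false positives.

    ``truths_per_image`` holds half-open pixel boxes (one per true
    cluster); the default ``center_in_box`` rule accepts a pair when
    either box contains the other's centre, which is tolerant of
    block-grid quantization.
    """
    if len(detections_per_image) != len(truths_per_image):
        raise ParameterError("detections and truths must cover the same images")
    n_images = len(detections_per_image)
    if n_images == 0:
        raise ParameterError("at least one image is required")

    n_true = 0
    n_detected = 0
    n_fp = 0
    records = []
    for img_i, (dets, truths) in enumerate(zip(detections_per_image, truths_per_image)):
        n_true += len(truths)
        candidate_pairs = []
        for d_i, det in enumerate(dets):
            det_box = tuple(float(v) for v in det.bbox_px)
            for t_i, truth in enumerate(truths):
                truth_box = tuple(float(v) for v in truth)
                if _matches(det_box, truth_box, match_rule, min_iou):
                    candidate_pairs.append(
                        (_overlap_area(det_box, truth_box), d_i, t_i)
                    )
        candidate_pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        claimed_truths: set[int] = set()
        matched_dets: set[int] = set()
        for _, d_i, t_i in candidate_pairs:
            if t_i in claimed_truths:
                continue
            claimed_truths.add(t_i)
            matched_dets.add(d_i)
        img_fp = len(dets) - len(matched_dets)
        n_detected += len(claimed_truths)
        n_fp += img_fp
        records.append(
            {
                "image": img_i,
                "n_detections": len(dets),
                "n_truths": len(truths),
                "n_matched_truths": len(claimed_truths),
                "n_false_positives": img_fp,
            }
        )
    return EvalResult(
        n_true_clusters=n_true,
        n_detected_true=n_detected,
        n_false_detections=n_fp,
        n_images=n_images,
        per_image_records=records,
    )
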