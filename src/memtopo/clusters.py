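"""Receptor cluster detection and per-cluster channel metrics.

Clusters are bright receptor structures: the receptor image is normalised by
its mean over the whole plasma membrane, pixels strictly above the cluster
threshold are labelled, components are kept within an inclusive area range,
and each cluster is assigned to the membrane region (protrusion or body) it
overlaps most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image_model import PipelineConfig
from .membrane import MembraneMasks

__all__ = ["ClusterRecord", "ClusterSet", "segment_clusters", "cluster_channel_ratio"]


@dataclass
class ClusterRecord:
    id: int
    area_px: int
    location: str  # protrusion | body | unassigned
    receptor_enrichment: float
    channel_metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusterSet:
    labels: np.ndarray
    clusters: list[ClusterRecord]

    def by_location(self, location: str) -> list[ClusterRecord]:
        return [c for c in self.clusters if c.location == location]

    def __len__(self) -> int:
        return len(self.clusters)


def segment_clusters(
    receptor_image: np.ndarray,
    mm: MembraneMasks,
    cfg: PipelineConfig,
    extra_channels: dict[str, np.ndarray] | None = None,
) -> ClusterSet:
    """Detect receptor clusters on the membrane-mean-normalised image.

    ``extra_channels`` maps a metric name to another channel image; for each
    cluster the membrane-normalised mean of that channel over the cluster
    pixels is recorded (e.g. a phosphatase channel for per-cluster ratios).
    """
    if not mm.valid:
        raise ValueError("cluster segmentation requires valid membrane masks")
    receptor_image = np.asarray(receptor_image, dtype=np.float64)
    if not mm.whole_membrane.any():
        raise ValueError("whole membrane mask is empty")
    membrane_mean = receptor_image[mm.whole_membrane].mean()
    if membrane_mean <= 0:
        raise ValueError("mean receptor intensity over the membrane is not positive")
    normalised = receptor_image / membrane_mean

    bright = normalised > cfg.cluster_threshold  # strictly above
    structure = ndi.generate_binary_structure(2, 2 if cfg.connectivity == 8 else 1)
    labels, n = ndi.label(bright, structure=structure)

    extra_norm: dict[str, np.ndarray] = {}
    for name, img in (extra_channels or {}).items():
        img = np.asarray(img, dtype=np.float64)
        mean = img[mm.whole_membrane].mean()
        extra_norm[name] = img / mean if mean > 0 else np.full_like(img, np.nan)

    out_labels = np.zeros_like(labels)
    records: list[ClusterRecord] = []
    next_id = 0
    for lbl in range(1, n + 1):
        comp = labels == lbl
        area = int(comp.sum())
        if not (cfg.cluster_area_min_px <= area <= cfg.cluster_area_max_px):
            continue
        overlap_p = int((comp & mm.protrusions).sum())
        overlap_b = int((comp & mm.body_membrane).sum())
        if overlap_p == 0 and overlap_b == 0:
            location = "unassigned"
        elif overlap_p >= overlap_b:  # tie goes to the smaller region
            location = "protrusion"
        else:
            location = "body"
        next_id += 1
        out_labels[comp] = next_id
        records.append(
            ClusterRecord(
                id=next_id,
                area_px=area,
                location=location,
                receptor_enrichment=float(normalised[comp].mean()),
                channel_metrics={
                    name: float(img[comp].mean()) for name, img in extra_norm.items()
                },
            )
        )
    return ClusterSet(labels=out_labels, clusters=records)


def cluster_channel_ratio(
    clusters: ClusterSet, numerator: str, denominator: str
) -> tuple[dict[str, float], int]:
    """Mean per-cluster numerator/denominator ratio, grouped by location.

    ``numerator``/``denominator`` name per-cluster metrics: either
    ``"receptor"`` (the receptor enrichment itself) or a key of
    ``channel_metrics``.  Clusters whose denominator is zero (or whose
    metric is missing) are excluded; the excluded count is returned.
    Locations with no usable cluster map to NaN.
    """

    def metric(c: ClusterRecord, name: str) -> float | None:
        if name == "receptor":
            return c.receptor_enrichment
        return c.channel_metrics.get(name)

    ratios: dict[str, list[float]] = {"protrusion": [], "body": []}
    excluded = 0
    for c in clusters.clusters:
        if c.location not in ratios:
            continue
        num, den = metric(c, numerator), metric(c, denominator)
        if num is None or den is None or den == 0 or not np.isfinite(num / den):
            excluded += 1
            continue
        ratios[c.location].append(num / den)
    means = {
        loc: (float(np.mean(vals)) if vals else float("nan"))
        for loc, vals in ratios.items()
    }
    return means, excluded
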