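"""Region-normalised intensity statistics and their time-course aggregation.

*Enrichment* of a protein in a membrane region is its mean intensity over
the region divided by its mean over the whole plasma membrane.  *Relative
enrichment* divides by the enrichment of a uniformly distributed membrane
marker in the same cell; at contact sets it is the ratio of contacting to
non-contacting enrichment.  *Membrane-bound* signal is the difference of
contacting minus non-contacting enrichment (a recruitment readout for
cytoplasm-dominated proteins), optionally normalised by a marker reference.
Uncertainties are standard errors propagated through each ratio/difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .image_model import UncertainValue, propagate_difference, propagate_ratio

__all__ = [
    "MetricRecord",
    "MetricTimecourse",
    "normalize_to_max",
    "region_mean",
    "enrichment",
    "enrichment_uncertain",
    "relative_enrichment",
    "contact_relative_enrichment",
    "membrane_bound",
    "relative_membrane_bound",
    "aggregate_window",
]

REGIONS = (
    "protrusion",
    "body",
    "protrusion_contact",
    "protrusion_noncontact",
    "body_contact",
    "body_noncontact",
    "whole_membrane",
)
METRICS = (
    "enrichment",
    "relative_enrichment",
    "contact_relative_enrichment",
    "membrane_bound",
    "relative_membrane_bound",
)
_CONTACT_METRICS = ("contact_relative_enrichment", "membrane_bound", "relative_membrane_bound")
_CONTACT_REGIONS = ("protrusion", "body")  # contact metrics are per region class


@dataclass
class MetricRecord:
    frame: int
    t_s: float
    region: str
    metric: str
    value: UncertainValue
    channel_role: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric in _CONTACT_METRICS and self.region not in _CONTACT_REGIONS:
            raise ValueError(f"{self.metric} is only defined per region class")


@dataclass
class MetricTimecourse:
    """Ordered metric records for one cell/interaction event."""

    records: list[MetricRecord] = field(default_factory=list)
    cell_id: str = "cell"
    replicate_id: str = "rep"
    frame_interval_s: float = 4.0
    t0_frame: int | None = None

    def append(self, record: MetricRecord) -> None:
        self.records.append(record)

    def select(
        self,
        metric: str | None = None,
        region: str | None = None,
        channel_role: str | None = None,
    ) -> list[MetricRecord]:
        out = self.records
        if metric is not None:
            out = [r for r in out if r.metric == metric]
        if region is not None:
            out = [r for r in out if r.region == region]
        if channel_role is not None:
            out = [r for r in out if r.channel_role == channel_role]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": self.cell_id,
                "replicate_id": self.replicate_id,
                "frame": r.frame,
                "t_s": r.t_s,
                "region": r.region,
                "metric": r.metric,
                "channel_role": r.channel_role,
                "value": r.value.value,
                "sem": r.value.sem,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "replicate_id",
                "frame",
                "t_s",
                "region",
                "metric",
                "channel_role",
                "value",
                "sem",
            ],
        )


# ---------------------------------------------------------------------------
# pixel statistics
# ---------------------------------------------------------------------------

def normalize_to_max(image: np.ndarray, whole_membrane: np.ndarray) -> np.ndarray:
    """Divide by the image maximum over the membrane mask."""
    image = np.asarray(image, dtype=np.float64)
    whole_membrane = np.asarray(whole_membrane, dtype=bool)
    if not whole_membrane.any():
        raise ValueError("whole membrane mask is empty")
    peak = image[whole_membrane].max()
    if peak <= 0:
        raise ValueError("membrane maximum is not positive")
    return image / peak


def region_mean(image: np.ndarray, region: np.ndarray) -> UncertainValue:
    """Mean +/- standard error of the image over a mask."""
    vals = np.asarray(image, dtype=np.float64)[np.asarray(region, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty region")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return UncertainValue(float(vals.mean()), sem)


def enrichment(
    image: np.ndarray, region: np.ndarray, whole_membrane: np.ndarray
) -> float:
    """mean(image | region) / mean(image | whole membrane)."""
    return enrichment_uncertain(image, region, whole_membrane).value


def enrichment_uncertain(
    image: np.ndarray, region: np.ndarray, whole_membrane: np.ndarray
) -> UncertainValue:
    region = np.asarray(region, dtype=bool)
    whole_membrane = np.asarray(whole_membrane, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    if not whole_membrane.any():
        raise ValueError("empty whole-membrane mask")
    denom = region_mean(image, whole_membrane)
    if denom.value <= 0:
        raise ValueError("whole-membrane mean is not positive")
    if np.array_equal(region, whole_membrane):
        return UncertainValue(1.0, 0.0)  # exact by definition
    return propagate_ratio(region_mean(image, region), denom)


def relative_enrichment(protein_e: float, reference_e: float) -> float:
    """Protein enrichment normalised by the membrane-marker enrichment."""
    if reference_e <= 0:
        raise ValueError("reference enrichment must be positive")
    return protein_e / reference_e


def contact_relative_enrichment(
    image: np.ndarray,
    region_contact: np.ndarray,
    region_noncontact: np.ndarray,
    whole_membrane: np.ndarray,
) -> float:
    """Enrichment at the contacting part of a region over the rest of it."""
    e_c = enrichment_uncertain(image, region_contact, whole_membrane)
    e_n = enrichment_uncertain(image, region_noncontact, whole_membrane)
    return propagate_ratio(e_c, e_n).value


def membrane_bound(
    image: np.ndarray,
    region_contact: np.ndarray,
    region_noncontact: np.ndarray,
    whole_membrane: np.ndarray,
) -> UncertainValue:
    """Difference of contacting minus non-contacting enrichment."""
    e_c = enrichment_uncertain(image, region_contact, whole_membrane)
    e_n = enrichment_uncertain(image, region_noncontact, whole_membrane)
    return propagate_difference(e_c, e_n)


def relative_membrane_bound(
    mb: UncertainValue, caax_reference: UncertainValue
) -> UncertainValue:
    """Membrane-bound signal normalised by the marker reference enrichment.

    The reference is an externally supplied constant (from a marker dataset)
    when the marker channel is absent from the stack being analysed.
    """
    if caax_reference is None:
        raise ValueError(
            "no membrane-marker reference configured; set caax_reference_enrichment"
        )
    if caax_reference.value <= 0:
        raise ValueError("marker reference enrichment must be positive")
    return propagate_ratio(mb, caax_reference)


def aggregate_window(
    tc: MetricTimecourse,
    metric: str,
    region: str,
    channel_role: str,
    window_s: tuple[float, float] = (0.0, 60.0),
) -> tuple[UncertainValue, int]:
    """Mean +/- s.e.m. of a metric over frames with t_s inside the window
    (inclusive at both ends).  Returns (aggregate, n_skipped) where skipped
    counts frames in the window whose value is missing (NaN).
    """
    if tc.t0_frame is None:
        raise ValueError("time zero undefined: cannot align the window")
    lo, hi = window_s
    recs = [
        r
        for r in tc.select(metric=metric, region=region, channel_role=channel_role)
        if lo <= r.t_s <= hi
    ]
    if not recs:
        raise ValueError("no frames in aggregation window")
    values = np.array([r.value.value for r in recs], dtype=np.float64)
    ok = np.isfinite(values)
    skipped = int((~ok).sum())
    values = values[ok]
    if values.size == 0:
        raise ValueError("all frames in window carry missing values")
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return UncertainValue(float(values.mean()), sem), skipped


def timecourses_to_frame(events: Iterable[MetricTimecourse]) -> pd.DataFrame:
    return pd.concat([tc.to_dataframe() for tc in events], ignore_index=True)
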