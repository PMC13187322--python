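"""End-to-end event processing and cross-event summaries.

``run_event`` takes one multi-channel time lapse through preprocessing,
membrane/target/cluster segmentation and metric extraction, aligning time to
the first detected contact.  ``summarise_events`` aggregates a window of the
resulting timecourses per event, per replicate and overall, and runs the
paired/unpaired two-sided t tests used for region and group comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ClusterSet, segment_clusters
from .contacts import (
    ContactMasks,
    compute_contacts,
    contact_area_fractions,
    detect_first_contact,
    segment_target,
)
from .image_model import (
    FrameStack,
    PipelineConfig,
    UncertainValue,
    average_channels,
    gaussian_blur,
    propagate_ratio,
    subtract_background,
)
from .membrane import MembraneMasks, segment_inner_body, segment_membrane
from .metrics import (
    MetricRecord,
    MetricTimecourse,
    enrichment_uncertain,
    normalize_to_max,
    propagate_difference,
)

__all__ = ["EventRejected", "EventResult", "run_event", "summarise_events", "SummaryResult"]


class EventRejected(RuntimeError):
    """Raised when no frame of an event could be segmented."""


@dataclass
class EventResult:
    timecourse: MetricTimecourse
    membrane_masks: list[MembraneMasks]
    contacts: list[ContactMasks | None]
    clusters: list[ClusterSet | None]
    target_masks: list[np.ndarray] | None
    t0_frame: int | None
    discarded_frames: list[int]
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)

    def contact_fractions(self, frame: int) -> tuple[float, float]:
        c = self.contacts[frame]
        if c is None:
            return (float("nan"), float("nan"))
        return contact_area_fractions(c)


def _preprocess_plane(plane: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    bg = subtract_background(
        plane, cfg.pre_rolling_ball_radius_px, kernel=cfg.rolling_ball_kernel
    )
    return gaussian_blur(bg, cfg.pre_blur_sigma_px)


def _try_enrichment(image, region, whole) -> UncertainValue | None:
    if not region.any() or not whole.any():
        return None
    try:
        return enrichment_uncertain(image, region, whole)
    except ValueError:
        return None


def run_event(
    stack: FrameStack,
    cfg: PipelineConfig,
    *,
    cell_id: str = "cell",
    replicate_id: str = "rep",
) -> EventResult:
    """Run the full per-event pipeline on one stack.

    Frames whose inner-body segmentation fails are discarded (recorded but
    excluded from metrics and contact detection).  Without a target channel
    the event is analysed in resting-cell mode: enrichment and relative
    enrichment only, time measured from frame 0.
    """
    n_frames = stack.n_frames
    shape = stack.spatial_shape
    seg_roles = [r for r in cfg.segmentation_channels if stack.has_role(r)]
    if not seg_roles:
        raise EventRejected(
            f"none of the configured segmentation channels {cfg.segmentation_channels} "
            "are present in the stack"
        )
    measured_roles = [
        r for r in stack.channel_roles.values() if r != "target"
    ]
    has_reference = stack.has_role("membrane_reference")
    has_target = stack.has_role("target")

    # preprocessing: per-channel measurement images
    measured: dict[str, list[np.ndarray]] = {
        role: [
            _preprocess_plane(stack.channel(role, f), cfg) for f in range(n_frames)
        ]
        for role in measured_roles
    }

    membrane_masks: list[MembraneMasks] = []
    discarded: list[int] = []
    for f in range(n_frames):
        seg = np.mean([measured[r][f] for r in seg_roles], axis=0)
        seg = gaussian_blur(seg, cfg.seg_blur_sigma_px)
        inner, ok = segment_inner_body(seg, cfg)
        if not ok:
            membrane_masks.append(MembraneMasks.invalid(shape))
            discarded.append(f)
            continue
        mm = segment_membrane(seg, inner, cfg)
        if not mm.valid or not mm.whole_membrane.any():
            membrane_masks.append(MembraneMasks.invalid(shape))
            discarded.append(f)
            continue
        membrane_masks.append(mm)

    if len(discarded) == n_frames:
        raise EventRejected(
            f"all {n_frames} frames discarded: inner-body segmentation failed everywhere"
        )

    target_masks: list[np.ndarray] | None = None
    contacts: list[ContactMasks | None] = [None] * n_frames
    t0: int | None = None
    if has_target:
        target_masks = segment_target(stack, cfg)
        for f in range(n_frames):
            if membrane_masks[f].valid:
                contacts[f] = compute_contacts(membrane_masks[f], target_masks[f])
        t0 = detect_first_contact(contacts, cfg)

    tc = MetricTimecourse(
        cell_id=cell_id,
        replicate_id=replicate_id,
        frame_interval_s=stack.frame_interval_s,
        t0_frame=t0,
    )
    clusters: list[ClusterSet | None] = [None] * n_frames

    for f in range(n_frames):
        mm = membrane_masks[f]
        if not mm.valid:
            continue
        t_s = (f - (t0 if t0 is not None else 0)) * stack.frame_interval_s
        whole = mm.whole_membrane

        images = {}
        for role in measured_roles:
            try:
                images[role] = normalize_to_max(measured[role][f], whole)
            except ValueError:  # membrane carries no signal in this channel
                images[role] = measured[role][f]

        region_masks = {"protrusion": mm.protrusions, "body": mm.body_membrane}
        e: dict[tuple[str, str], UncertainValue] = {}
        for role, region in itertools.product(measured_roles, region_masks):
            val = _try_enrichment(images[role], region_masks[region], whole)
            if val is None:
                continue
            e[(role, region)] = val
            tc.append(MetricRecord(f, t_s, region, "enrichment", val, role))
        for role in measured_roles:
            tc.append(
                MetricRecord(
                    f, t_s, "whole_membrane", "enrichment", UncertainValue(1.0, 0.0), role
                )
            )
        if has_reference:
            for role, region in itertools.product(measured_roles, region_masks):
                if role == "membrane_reference":
                    continue
                num, den = e.get((role, region)), e.get(("membrane_reference", region))
                if num is None or den is None or den.value <= 0:
                    continue
                tc.append(
                    MetricRecord(
                        f, t_s, region, "relative_enrichment",
                        propagate_ratio(num, den), role,
                    )
                )

        c = contacts[f]
        if c is not None:
            sub = {
                "protrusion": (c.protrusion_contact, c.protrusion_noncontact),
                "body": (c.body_contact, c.body_noncontact),
            }
            for role, region in itertools.product(measured_roles, sub):
                cm, nm = sub[region]
                ec = _try_enrichment(images[role], cm, whole)
                en = _try_enrichment(images[role], nm, whole)
                if ec is None or en is None or en.value <= 0:
                    continue
                tc.append(
                    MetricRecord(
                        f, t_s, region, "contact_relative_enrichment",
                        propagate_ratio(ec, en), role,
                    )
                )
                mb = propagate_difference(ec, en)
                tc.append(MetricRecord(f, t_s, region, "membrane_bound", mb, role))
                ref = None
                if has_reference and role != "membrane_reference":
                    ref = e.get(("membrane_reference", region))
                if ref is None:
                    ref = cfg.caax_reference_enrichment
                if ref is not None and ref.value > 0 and role != "membrane_reference":
                    tc.append(
                        MetricRecord(
                            f, t_s, region, "relative_membrane_bound",
                            propagate_ratio(mb, ref), role,
                        )
                    )

        if stack.has_role("receptor"):
            extra = {
                role: images[role]
                for role in measured_roles
                if role != "receptor"
            }
            try:
                clusters[f] = segment_clusters(
                    images["receptor"], mm, cfg, extra_channels=extra
                )
            except ValueError:
                clusters[f] = None

    provenance = {
        "config_hash": cfg.config_hash(),
        "discarded_frames": list(discarded),
        "discard_rule": "inner-body segmentation failed",
        "n_frames": n_frames,
        "t0_frame": t0,
        "segmentation_channels": seg_roles,
    }
    return EventResult(
        timecourse=tc,
        membrane_masks=membrane_masks,
        contacts=contacts,
        clusters=clusters,
        target_masks=target_masks,
        t0_frame=t0,
        discarded_frames=discarded,
        config=cfg,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# cross-event summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryResult:
    event_means: pd.DataFrame
    replicate_means: pd.DataFrame
    overall: pd.DataFrame
    paired_tests: pd.DataFrame
    unpaired_tests: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def summarise_events(
    events: Sequence[MetricTimecourse],
    window_s: tuple[float, float] = (0.0, 60.0),
    group_labels: Sequence[str] | None = None,
) -> SummaryResult:
    """Window means per event / replicate / overall, plus two-sided t tests.

    Paired t tests compare protrusion vs body within events (per metric and
    channel); unpaired t tests compare groups in ``group_labels`` (defaults
    to each event's replicate label) for each metric/region/channel.  P
    values are reported raw, without multiplicity adjustment.
    """
    from .metrics import aggregate_window

    if group_labels is None:
        group_labels = [tc.replicate_id for tc in events]
    if len(group_labels) != len(events):
        raise ValueError("one group label per event required")
    warnings: list[str] = []

    rows = []
    for i, tc in enumerate(events):
        combos = {(r.metric, r.region, r.channel_role) for r in tc.records}
        for metric, region, role in sorted(combos):
            if tc.t0_frame is None and metric in (
                "contact_relative_enrichment",
                "membrane_bound",
                "relative_membrane_bound",
            ):
                continue
            try:
                if tc.t0_frame is None:
                    recs = [
                        r.value.value
                        for r in tc.select(metric=metric, region=region, channel_role=role)
                    ]
                    vals = np.array([v for v in recs if np.isfinite(v)])
                    if vals.size == 0:
                        continue
                    agg = UncertainValue(
                        float(vals.mean()),
                        float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                    )
                    skipped = len(recs) - vals.size
                else:
                    agg, skipped = aggregate_window(
                        tc, metric, region, role, window_s=window_s
                    )
            except ValueError:
                continue
            rows.append(
                {
                    "event": i,
                    "cell_id": tc.cell_id,
                    "replicate_id": tc.replicate_id,
                    "group": group_labels[i],
                    "metric": metric,
                    "region": region,
                    "channel_role": role,
                    "mean": agg.value,
                    "sem": agg.sem,
                    "skipped_frames": skipped,
                }
            )
    event_means = pd.DataFrame(
        rows,
        columns=[
            "event", "cell_id", "replicate_id", "group", "metric", "region",
            "channel_role", "mean", "sem", "skipped_frames",
        ],
    )

    if event_means.empty:
        return SummaryResult(
            event_means, pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
            ["no aggregatable records"],
        )

    keys = ["metric", "region", "channel_role"]
    replicate_means = (
        event_means.groupby(["replicate_id", *keys], as_index=False)["mean"]
        .mean()
        .rename(columns={"mean": "replicate_mean"})
    )
    overall = (
        event_means.groupby(keys)["mean"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n_events", "std": "sd"})
    )

    # paired: protrusion vs body within events
    paired_rows = []
    for (metric, role), sub in event_means.groupby(["metric", "channel_role"]):
        piv = sub.pivot_table(index="event", columns="region", values="mean")
        if not {"protrusion", "body"} <= set(piv.columns):
            continue
        piv = piv.dropna(subset=["protrusion", "body"])
        if len(piv) < 2:
            warnings.append(f"paired test skipped for {metric}/{role}: <2 events")
            continue
        t, p = _paired_t(piv["protrusion"].to_numpy(), piv["body"].to_numpy())
        paired_rows.append(
            {
                "metric": metric, "channel_role": role, "comparison": "protrusion_vs_body",
                "n_pairs": len(piv), "t": t, "p": p,
            }
        )
    paired_tests = pd.DataFrame(
        paired_rows, columns=["metric", "channel_role", "comparison", "n_pairs", "t", "p"]
    )

    # unpaired: between groups
    unpaired_rows = []
    groups = sorted(set(group_labels))
    if len(groups) >= 2:
        for combo, sub in event_means.groupby(keys):
            for ga, gb in itertools.combinations(groups, 2):
                a = sub.loc[sub["group"] == ga, "mean"].to_numpy()
                b = sub.loc[sub["group"] == gb, "mean"].to_numpy()
                if a.size < 2 or b.size < 2:
                    continue
                t, p = stats.ttest_ind(a, b)
                unpaired_rows.append(
                    {
                        "metric": combo[0], "region": combo[1], "channel_role": combo[2],
                        "group_a": ga, "group_b": gb, "n_a": a.size, "n_b": b.size,
                        "t": float(t), "p": float(p),
                    }
                )
    elif len(events) < 2:
        warnings.append("single event: statistical tests skipped")
    unpaired_tests = pd.DataFrame(
        unpaired_rows,
        columns=["metric", "region", "channel_role", "group_a", "group_b", "n_a", "n_b", "t", "p"],
    )
    return SummaryResult(
        event_means, replicate_means, overall, paired_tests, unpaired_tests, warnings
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def mask_statistics(result: EventResult) -> pd.DataFrame:
    """Per-frame region areas (and contact areas/percentages when present)."""
    rows = []
    for f, mm in enumerate(result.membrane_masks):
        if not mm.valid:
            continue
        for region, mask in (
            ("inner_body", mm.inner_body),
            ("protrusion", mm.protrusions),
            ("body", mm.body_membrane),
            ("whole_membrane", mm.whole_membrane),
        ):
            rows.append({"frame": f, "region": region, "area_px": int(mask.sum())})
        c = result.contacts[f]
        if c is not None:
            p_pct, b_pct = contact_area_fractions(c)
            rows.append(
                {
                    "frame": f, "region": "protrusion_contact",
                    "area_px": int(c.protrusion_contact.sum()), "contact_pct": p_pct,
                }
            )
            rows.append(
                {
                    "frame": f, "region": "body_contact",
                    "area_px": int(c.body_contact.sum()), "contact_pct": b_pct,
                }
            )
    return pd.DataFrame(rows)


def cluster_table(result: EventResult) -> pd.DataFrame:
    rows = []
    for f, cs in enumerate(result.clusters):
        if cs is None:
            continue
        for c in cs.clusters:
            row = {
                "frame": f,
                "cluster_id": c.id,
                "area_px": c.area_px,
                "location": c.location,
                "receptor_enrichment": c.receptor_enrichment,
            }
            row.update({f"{k}_enrichment": v for k, v in c.channel_metrics.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def save_event(result: EventResult, out_dir: str | Path, stem: str = "event") -> None:
    """Write the metric table, mask statistics, cluster table and sidecar."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.timecourse.to_dataframe().to_csv(out / f"{stem}_metrics.csv", index=False)
    mask_statistics(result).to_csv(out / f"{stem}_mask_stats.csv", index=False)
    ct = cluster_table(result)
    if not ct.empty:
        ct.to_csv(out / f"{stem}_clusters.csv", index=False)
    sidecar = dict(result.provenance)
    sidecar["config"] = result.config.to_dict()
    (out / f"{stem}_provenance.json").write_text(json.dumps(sidecar, indent=2, default=str))
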