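"""Target-cell segmentation and contact partitioning.

The target (stained with a whole-membrane dye) is thresholded with the
moment-preserving method computed once on the preprocessed *last* frame of
the stack — the frame in which the target is most completely visible — and
that scalar threshold is applied to every frame.  Membrane regions are then
split into target-contacting and non-contacting parts by mask intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_model import FrameStack, PipelineConfig, gaussian_blur, subtract_background
from .membrane import MembraneMasks
from .thresholds import moments_threshold

__all__ = [
    "ContactMasks",
    "segment_target",
    "compute_contacts",
    "detect_first_contact",
    "contact_area_fractions",
]


@dataclass
class ContactMasks:
    target: np.ndarray
    protrusion_contact: np.ndarray
    protrusion_noncontact: np.ndarray
    body_contact: np.ndarray
    body_noncontact: np.ndarray

    def total_contact_px(self) -> int:
        return int(self.protrusion_contact.sum() + self.body_contact.sum())

    def check_invariants(self, mm: MembraneMasks) -> None:
        assert np.array_equal(
            self.protrusion_contact | self.protrusion_noncontact, mm.protrusions
        )
        assert not np.any(self.protrusion_contact & self.protrusion_noncontact)
        assert np.array_equal(self.body_contact | self.body_noncontact, mm.body_membrane)
        assert not np.any(self.body_contact & self.body_noncontact)
        assert np.all(self.target[self.protrusion_contact])
        assert np.all(self.target[self.body_contact])


def preprocess_target_frame(frame: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    bg = subtract_background(
        frame, cfg.pre_rolling_ball_radius_px, kernel=cfg.rolling_ball_kernel
    )
    return gaussian_blur(bg, cfg.seg_blur_sigma_px)


def segment_target(stack: FrameStack, cfg: PipelineConfig) -> list[np.ndarray]:
    """Per-frame target masks from a stack-wide last-frame Moments threshold."""
    if not stack.has_role("target"):
        raise ValueError("stack has no target-role channel")
    frames = [
        preprocess_target_frame(stack.channel("target", f), cfg)
        for f in range(stack.n_frames)
    ]
    thr = moments_threshold(frames[-1])
    return [f > thr for f in frames]


def compute_contacts(mm: MembraneMasks, target: np.ndarray) -> ContactMasks:
    """Intersect membrane regions with the target footprint."""
    if not mm.valid:
        raise ValueError("cannot compute contacts for invalid membrane masks")
    target = np.asarray(target, dtype=bool)
    p_contact = mm.protrusions & target
    b_contact = mm.body_membrane & target
    return ContactMasks(
        target=target,
        protrusion_contact=p_contact,
        protrusion_noncontact=mm.protrusions & ~p_contact,
        body_contact=b_contact,
        body_noncontact=mm.body_membrane & ~b_contact,
    )


def detect_first_contact(
    contacts: Sequence[ContactMasks | None], cfg: PipelineConfig
) -> int | None:
    """Smallest frame index whose contact area reaches min_contact_px.

    ``None`` entries (frames discarded by inner-body segmentation) are
    skipped; returns None when no frame ever reaches the threshold.
    """
    if len(contacts) == 0:
        raise ValueError("empty contact sequence")
    for idx, c in enumerate(contacts):
        if c is None:
            continue
        if c.total_contact_px() >= cfg.min_contact_px:
            return idx
    return None


def contact_area_fractions(c: ContactMasks) -> tuple[float, float]:
    """Percentages of total contact area on protrusions vs body membrane.

    Undefined (NaN, NaN) when there is no contact at all.
    """
    p = float(c.protrusion_contact.sum())
    b = float(c.body_contact.sum())
    total = p + b
    if total == 0:
        return (float("nan"), float("nan"))
    return (100.0 * p / total, 100.0 * b / total)
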