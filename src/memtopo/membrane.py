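"""Membrane topography segmentation.

Turns a channel-averaged, blurred segmentation image into the region masks
used everywhere downstream: the dark cell interior ("inner body"), its
dilation-based neighbourhood, thin tubular protrusions, the main-body
membrane shell, and their union (the whole plasma membrane).

The segmentation runs in two streams: the inner body is found by enhancing
dark enclosed holes in the inverted image, and membrane structures by ridge
("tubeness") enhancement; protrusions are the ridge pixels that survive
subtraction of the dilated inner body, restriction to the neighbourhood,
and removal of single-pixel objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from .image_model import PipelineConfig, subtract_background
from .thresholds import auto_threshold

__all__ = [
    "MembraneMasks",
    "segment_inner_body",
    "dilate_mask",
    "enhance_tubeness",
    "segment_membrane",
]


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


@dataclass
class MembraneMasks:
    """Per-frame binary region masks; ``valid`` is False when the inner body
    could not be detected (such frames are discarded upstream)."""

    inner_body: np.ndarray
    neighbourhood: np.ndarray
    protrusions: np.ndarray
    body_membrane: np.ndarray
    whole_membrane: np.ndarray
    valid: bool = True

    @classmethod
    def invalid(cls, shape: tuple[int, int]) -> "MembraneMasks":
        empty = np.zeros(shape, dtype=bool)
        return cls(
            inner_body=empty.copy(),
            neighbourhood=empty.copy(),
            protrusions=empty.copy(),
            body_membrane=empty.copy(),
            whole_membrane=empty.copy(),
            valid=False,
        )

    def check_invariants(self) -> None:
        """Raise AssertionError if any mask-algebra invariant is violated."""
        assert not np.any(self.protrusions & self.body_membrane), "protrusion/body overlap"
        assert np.array_equal(
            self.whole_membrane, self.protrusions | self.body_membrane
        ), "whole_membrane != protrusions | body_membrane"
        assert not np.any(self.protrusions & self.inner_body), "protrusion/inner overlap"
        assert np.all(self.neighbourhood[self.protrusions]), "protrusion outside neighbourhood"
        assert np.all(self.neighbourhood[self.inner_body]), "inner body outside neighbourhood"
        if not self.valid:
            for m in (
                self.inner_body,
                self.neighbourhood,
                self.protrusions,
                self.body_membrane,
                self.whole_membrane,
            ):
                assert not m.any(), "invalid masks must be empty"


def segment_inner_body(
    seg_image: np.ndarray, cfg: PipelineConfig
) -> tuple[np.ndarray, bool]:
    """Detect the dark cell interior.

    The image is inverted, dark enclosed holes are enhanced by rolling-ball
    background subtraction (flat-disc dialect: an unbounded exterior plateau
    is removed while an enclosed hole smaller than the structuring radius is
    retained in full), thresholded, area-filtered, hole-filled, and the
    largest surviving component is returned.  Failure (no component passes
    the area filter) is reported via the flag, not an exception.
    """
    seg_image = np.asarray(seg_image, dtype=np.float64)
    shape = seg_image.shape
    if seg_image.max() <= seg_image.min():
        return np.zeros(shape, dtype=bool), False
    inverted = seg_image.max() - seg_image
    enhanced = subtract_background(inverted, cfg.holes_radius_px, kernel="disc")
    if enhanced.max() <= 0:
        return np.zeros(shape, dtype=bool), False
    thr = auto_threshold(enhanced, cfg.membrane_threshold_method, cfg.fixed_threshold)
    mask = enhanced > thr
    labels, n = ndi.label(mask, structure=_structure(cfg.connectivity))
    if n == 0:
        return np.zeros(shape, dtype=bool), False
    areas = ndi.sum_labels(np.ones(shape), labels, index=np.arange(1, n + 1))
    keep = np.nonzero(areas >= cfg.inner_body_min_area_px)[0]
    if keep.size == 0:
        return np.zeros(shape, dtype=bool), False
    # largest area, ties broken by lowest label index
    best = keep[np.argmax(areas[keep])] + 1
    body = ndi.binary_fill_holes(labels == best)
    return body, True


def dilate_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Dilate with an exact Euclidean disc of the given radius.

    Implemented via the distance transform of the complement, so a pixel is
    included iff its distance to the input mask is <= radius_px.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if radius_px == 0 or not mask.any():
        return mask.copy()
    dist = ndi.distance_transform_edt(~mask)
    return dist <= radius_px


def enhance_tubeness(image: np.ndarray, scale_px: float) -> np.ndarray:
    """Single-scale ridge score: max(0, -lambda2) * scale^2 of the Hessian.

    lambda2 is the more negative Hessian eigenvalue after Gaussian smoothing
    at scale_px, so bright tubular structures on a dark background score
    high and flat regions score zero.
    """
    if scale_px <= 0:
        raise ValueError("scale_px must be positive")
    image = np.asarray(image, dtype=np.float64)
    H = hessian_matrix(
        image, sigma=scale_px, mode="reflect", use_gaussian_derivatives=True
    )
    eigvals = hessian_matrix_eigvals(H)  # sorted descending: eigvals[1] most negative
    return np.maximum(0.0, -eigvals[1]) * scale_px**2


def _drop_small_components(
    mask: np.ndarray, min_area_exclusive: int, connectivity: int
) -> np.ndarray:
    """Remove connected components with area <= min_area_exclusive."""
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    if n == 0:
        return mask.copy()
    areas = ndi.sum_labels(np.ones_like(mask, dtype=np.float64), labels, np.arange(1, n + 1))
    good = np.nonzero(areas > min_area_exclusive)[0] + 1
    return np.isin(labels, good)


def segment_membrane(
    seg_image: np.ndarray, inner_body: np.ndarray, cfg: PipelineConfig
) -> MembraneMasks:
    """Build all membrane region masks from the segmentation image.

    Ridge-enhanced structures are thresholded; protrusion candidates are the
    ridge pixels left after subtracting the body-dilated inner mask, clipped
    to the neighbourhood and stripped of single-pixel objects.  The body
    membrane is what remains of the ridge mask once the inner body and the
    protrusions are removed, and the whole membrane is the union.
    """
    seg_image = np.asarray(seg_image, dtype=np.float64)
    inner_body = np.asarray(inner_body, dtype=bool)
    if not inner_body.any():
        return MembraneMasks.invalid(seg_image.shape)

    tub = enhance_tubeness(seg_image, cfg.tubeness_scale_px)
    thr = auto_threshold(tub, cfg.membrane_threshold_method, cfg.fixed_threshold)
    neurites = tub > thr

    body_dilated = dilate_mask(inner_body, cfg.body_dilate_px)
    neighbourhood = dilate_mask(inner_body, cfg.neighbourhood_dilate_px)

    candidates = neurites & ~body_dilated
    candidates &= neighbourhood
    protrusions = _drop_small_components(candidates, 1, cfg.connectivity)

    body_membrane = neurites & ~inner_body & ~protrusions
    whole_membrane = protrusions | body_membrane
    return MembraneMasks(
        inner_body=inner_body,
        neighbourhood=neighbourhood,
        protrusions=protrusions,
        body_membrane=body_membrane,
        whole_membrane=whole_membrane,
        valid=True,
    )
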