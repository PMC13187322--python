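"""Core data model, TIFF I/O and shared preprocessing operators.

Images are plain :class:`numpy.ndarray` objects; a *binary mask* is a boolean
array with the same spatial shape as the frames it refers to.  All operators
promote to ``float64``, preserve shape, and keep intensities non-negative.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.restoration import rolling_ball
from skimage.transform import resize

__all__ = [
    "ROLES",
    "FrameStack",
    "PipelineConfig",
    "UncertainValue",
    "read_stack",
    "write_stack",
    "write_masks",
    "subtract_background",
    "gaussian_blur",
    "average_channels",
    "propagate_difference",
    "propagate_ratio",
]

#: channel roles understood by the pipeline
ROLES = ("membrane_reference", "receptor", "protein", "target")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """Multi-channel 2D time lapse with channel roles and calibration.

    ``data`` is indexed ``(frame, channel, y, x)`` and holds non-negative
    floating-point intensities.
    """

    data: np.ndarray
    channel_roles: dict[int, str]
    pixel_size_nm: float = 70.0
    frame_interval_s: float = 4.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (frame, channel, y, x); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative intensities")
        n_ch = self.data.shape[1]
        seen_roles: set[str] = set()
        for idx, role in self.channel_roles.items():
            if not (0 <= int(idx) < n_ch):
                raise ValueError(f"role {role!r} maps to channel {idx}, stack has {n_ch}")
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")
            if role in seen_roles:
                raise ValueError(f"duplicate channel role {role!r}")
            seen_roles.add(role)

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles.values()

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return int(idx)
        raise KeyError(f"stack has no channel with role {role!r}")

    def channel(self, role: str, frame: int | None = None) -> np.ndarray:
        idx = self.channel_index(role)
        if frame is None:
            return self.data[:, idx]
        return self.data[frame, idx]


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation/quantification pipeline.

    Defaults mirror the published parameter set where one is printed
    (dilations 9 / 35 px, rolling-ball radius 50 px, cluster threshold 2,
    cluster area range [5, 100] px); the remaining values are documented
    pipeline choices.
    """

    pre_rolling_ball_radius_px: int = 50
    pre_blur_sigma_px: float = 1.0
    seg_blur_sigma_px: float = 2.0
    body_dilate_px: int = 9
    neighbourhood_dilate_px: int = 35
    tubeness_scale_px: float = 1.0
    membrane_threshold_method: str = "otsu"  # otsu | moments | fixed
    fixed_threshold: float | None = None
    holes_radius_px: int = 25
    inner_body_min_area_px: int = 5000
    cluster_threshold: float = 2.0
    cluster_area_min_px: int = 5
    cluster_area_max_px: int = 100
    min_contact_px: int = 1
    segmentation_channels: tuple[str, ...] = ("membrane_reference", "receptor")
    caax_reference_enrichment: "UncertainValue | None" = None
    connectivity: int = 8
    rolling_ball_kernel: str = "disc"  # disc | ball
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pre_rolling_ball_radius_px",
            "holes_radius_px",
            "inner_body_min_area_px",
            "cluster_area_min_px",
            "cluster_area_max_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.body_dilate_px < 0 or self.neighbourhood_dilate_px < 0:
            raise ValueError("dilation radii must be non-negative")
        if self.cluster_area_min_px > self.cluster_area_max_px:
            raise ValueError("cluster_area_min_px must not exceed cluster_area_max_px")
        if self.cluster_threshold <= 0:
            raise ValueError("cluster_threshold must be positive")
        if self.membrane_threshold_method not in ("otsu", "moments", "fixed"):
            raise ValueError("membrane_threshold_method must be otsu|moments|fixed")
        if self.membrane_threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.rolling_ball_kernel not in ("ball", "disc"):
            raise ValueError("rolling_ball_kernel must be 'ball' or 'disc'")
        self.segmentation_channels = tuple(self.segmentation_channels)
        for role in self.segmentation_channels:
            if role not in ROLES:
                raise ValueError(f"unknown segmentation channel role {role!r}")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation_channels"] = list(self.segmentation_channels)
        if self.caax_reference_enrichment is not None:
            d["caax_reference_enrichment"] = {
                "value": self.caax_reference_enrichment.value,
                "sem": self.caax_reference_enrichment.sem,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        ref = d.get("caax_reference_enrichment")
        if isinstance(ref, Mapping):
            d["caax_reference_enrichment"] = UncertainValue(ref["value"], ref["sem"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class UncertainValue:
    """A scalar with a standard error, supporting first-order propagation."""

    value: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")

    def __sub__(self, other: "UncertainValue") -> "UncertainValue":
        return propagate_difference(self, other)

    def __truediv__(self, other: "UncertainValue") -> "UncertainValue":
        return propagate_ratio(self, other)


def propagate_difference(a: UncertainValue, b: UncertainValue) -> UncertainValue:
    """a - b with variances added."""
    return UncertainValue(a.value - b.value, math.hypot(a.sem, b.sem))


def propagate_ratio(a: UncertainValue, b: UncertainValue) -> UncertainValue:
    """a / b with relative variances added.

    A zero-valued numerator (where the relative error is undefined) falls
    back to ``sem = a.sem / |b.value|``.
    """
    if b.value == 0:
        raise ZeroDivisionError("ratio by zero-valued denominator")
    value = a.value / b.value
    if a.value == 0:
        return UncertainValue(0.0, a.sem / abs(b.value))
    rel = math.hypot(a.sem / a.value, b.sem / b.value)
    return UncertainValue(value, abs(value) * rel)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    channel_roles: Mapping[int, str],
    *,
    pixel_size_nm: float = 70.0,
    frame_interval_s: float = 4.0,
) -> FrameStack:
    """Read a TIFF into a FrameStack with axes normalised to (T, C, Y, X).

    Axis interpretation uses the TIFF series axes string when available and
    otherwise disambiguates 3D arrays with the declared channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_declared = len(channel_roles)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. "TCYX", "CYX", "YX", "QYX"

    arr = np.asarray(arr)
    axes = axes.upper().replace("S", "C").replace("I", "Q").replace("Z", "Q")
    if arr.ndim == 2:
        data = arr[None, None]
    elif arr.ndim == 3:
        if axes in ("CYX",):
            data = arr[None]
        elif axes in ("TYX",):
            data = arr[:, None]
        elif arr.shape[0] == n_declared:
            data = arr[None]
        else:
            data = arr[:, None]
    elif arr.ndim == 4:
        if axes == "CTYX":
            arr = arr.transpose(1, 0, 2, 3)
        data = arr
    else:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} dimensions as 2D frames")

    if data.shape[1] != n_declared:
        raise ValueError(
            f"declared {n_declared} channel roles but file has {data.shape[1]} channels"
        )
    return FrameStack(
        data=np.clip(data.astype(np.float64), 0, None),
        channel_roles=dict(channel_roles),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
    )


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a FrameStack as a TCYX hyperstack TIFF (float32)."""
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        imagej=False,
        photometric="minisblack",
        metadata={"axes": "TCYX"},
    )


def write_masks(path: str | Path, masks: Sequence[np.ndarray]) -> None:
    """Write binary masks as an 8-bit (0/255) multi-page TIFF."""
    arr = np.stack([np.asarray(m, dtype=bool) for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(str(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# preprocessing operators
# ---------------------------------------------------------------------------

def _block_min(image: np.ndarray, factor: int) -> np.ndarray:
    h, w = image.shape
    ph, pw = (-h) % factor, (-w) % factor
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")
    blocks = padded.reshape(padded.shape[0] // factor, factor, padded.shape[1] // factor, factor)
    return blocks.min(axis=(1, 3))


def _shrink_factor(radius: int) -> int:
    # mirrors the ImageJ strategy of rolling the ball on a shrunken image
    if radius <= 10:
        return 1
    if radius <= 30:
        return 2
    return 4


def rolling_ball_background(
    image: np.ndarray, radius_px: int, kernel: str = "disc"
) -> np.ndarray:
    """Rolling-ball background estimate.

    ``kernel='disc'`` (default) is the flat-top dialect — a grayscale
    opening with a disc structuring element — which commutes with positive
    intensity rescaling, so every downstream ratio metric is exactly
    scale-invariant.  ``kernel='ball'`` rolls a true ball under the
    intensity surface (Fiji-style).  Large radii are computed on a
    block-minimum-shrunken image, as in ImageJ.
    """
    image = np.asarray(image, dtype=np.float64)
    if kernel not in ("ball", "disc"):
        raise ValueError("kernel must be 'ball' or 'disc'")
    shrink = _shrink_factor(radius_px)
    if shrink == 1:
        if kernel == "ball":
            return rolling_ball(image, radius=radius_px)
        return ndi.grey_opening(image, footprint=disk(radius_px))
    small = _block_min(image, shrink)
    r_small = max(1, int(round(radius_px / shrink)))
    if kernel == "ball":
        bg_small = rolling_ball(small, radius=radius_px / shrink)
    else:
        bg_small = ndi.grey_opening(small, footprint=disk(r_small))
    h, w = image.shape
    ph, pw = (-h) % shrink, (-w) % shrink
    bg = resize(
        bg_small, (h + ph, w + pw), order=1, mode="edge", anti_aliasing=False
    )[:h, :w]
    return np.minimum(bg, image.max())


def subtract_background(
    image: np.ndarray, radius_px: int, kernel: str = "disc"
) -> np.ndarray:
    """Subtract a rolling-ball background estimate, clamping at zero."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("subtract_background expects a 2D image")
    bg = rolling_ball_background(image, radius_px, kernel=kernel)
    return np.clip(image - bg, 0.0, None)


def gaussian_blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian filter with reflective boundaries; ``sigma_px=0`` is identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    image = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma=sigma_px, mode="reflect")


def average_channels(
    stack: FrameStack, roles: Sequence[str] | set[str], frame: int
) -> np.ndarray:
    """Pixelwise mean of the channels playing the given roles in one frame."""
    roles = list(roles)
    if not roles:
        raise ValueError("roles must be non-empty")
    planes = [stack.channel(role, frame) for role in roles]
    return np.mean(planes, axis=0)
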