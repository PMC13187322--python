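"""Ground-truthed synthetic fluorescence time lapses.

Scenes contain a roughly convex cell whose membrane is a thin bright shell,
straight tubular protrusions radiating from the body, an optional target
half-plane approaching from the right, optional bright receptor clusters
nucleating at contact sites, and Poisson + Gaussian noise.  Every frame
carries exact truth masks and the analytic signal model, so each pipeline
stage can be validated against planted parameters without any microscopy
data.

Determinism: geometry uses the substream ``[seed, 1]``, cluster placement
``[seed, 3]`` and per-(frame, channel) noise ``[seed, 2, frame, channel]``,
so identical parameters render bit-identical stacks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image_model import FrameStack, gaussian_blur
from .membrane import MembraneMasks, dilate_mask

__all__ = [
    "RegionFactors",
    "TargetSpec",
    "ClusterSpec",
    "SyntheticSceneParams",
    "SyntheticScene",
    "generate_scene",
    "truth_metrics",
    "photon_scale_for_snr",
    "default_channel_factors",
]

_CHANNEL_ORDER = ("membrane_reference", "receptor", "protein", "target")


@dataclass
class RegionFactors:
    """Multiplicative intensity factors per scene region for one channel.

    Contact factors default to the corresponding non-contact factor (no
    redistribution on contact).  Factors are relative to the membrane
    amplitude of the scene.
    """

    body: float = 1.0
    protrusion: float = 1.0
    body_contact: float | None = None
    protrusion_contact: float | None = None
    cytoplasm: float = 0.15
    background: float = 0.02

    def resolved(self) -> "RegionFactors":
        return RegionFactors(
            body=self.body,
            protrusion=self.protrusion,
            body_contact=self.body if self.body_contact is None else self.body_contact,
            protrusion_contact=(
                self.protrusion if self.protrusion_contact is None else self.protrusion_contact
            ),
            cytoplasm=self.cytoplasm,
            background=self.background,
        )

    def validate(self) -> None:
        for f in dataclasses.asdict(self).values():
            if f is not None and f < 0:
                raise ValueError("region factors must be non-negative")

    def is_uniform_marker(self) -> bool:
        r = self.resolved()
        return r.body == r.protrusion == r.body_contact == r.protrusion_contact


def default_channel_factors() -> dict[str, RegionFactors]:
    return {
        "membrane_reference": RegionFactors(),
        "receptor": RegionFactors(),
        "protein": RegionFactors(),
    }


@dataclass
class TargetSpec:
    """Half-plane target approaching from +x.

    At ``onset_frame`` the target boundary covers exactly ``overlap_px``
    columns of the rightmost membrane structure; each later frame it
    advances by ``speed_px_per_frame`` (never past the cell centre, so
    non-contacting membrane always remains).
    """

    onset_frame: int | None = 5
    speed_px_per_frame: float = 8.0
    overlap_px: int = 4


@dataclass
class ClusterSpec:
    """Bright receptor clusters nucleating ``delay_frames`` after contact.

    ``areas_px`` (exact pixel areas, grown as compact blobs) overrides
    ``radius_px``.  Without a target the clusters are planted on the
    membrane from frame 0.
    """

    count: int = 5
    amplitude: float = 3.0  # x mean membrane intensity
    radius_px: float = 3.0
    delay_frames: int = 1
    areas_px: Sequence[int] | None = None
    location: str = "any"  # any | body | protrusion
    channel_roles: tuple[str, ...] = ("receptor",)
    #: per-role cluster amplitude (x membrane mean); overrides amplitude/channel_roles
    channel_amplitudes: dict[str, float] | None = None

    def amplitude_map(self) -> dict[str, float]:
        if self.channel_amplitudes is not None:
            return dict(self.channel_amplitudes)
        return {role: self.amplitude for role in self.channel_roles}


@dataclass
class SyntheticSceneParams:
    field_size_px: int = 512
    pixel_size_nm: float = 70.0
    body_radius_px: float = 60.0
    shell_thickness_px: float = 3.0
    n_protrusions: int = 8
    protrusion_length_px: tuple[float, float] = (15.0, 25.0)
    protrusion_width_px: float = 3.0
    neighbourhood_px: int = 35
    membrane_amplitude: float = 100.0
    channel_factors: dict[str, RegionFactors] = field(default_factory=default_channel_factors)
    protrusion_enrichment: dict[str, float] = field(default_factory=dict)
    target: TargetSpec | None = None
    cluster_spec: ClusterSpec | None = None
    psf_sigma_px: float = 1.0
    photon_scale: float | None = None  # None: no shot noise
    read_sigma: float = 0.0
    n_frames: int = 10
    frame_interval_s: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.body_radius_px <= 0 or self.shell_thickness_px <= 0:
            raise ValueError("body radius and shell thickness must be positive")
        lo, hi = self.protrusion_length_px
        if lo <= 0 or hi < lo:
            raise ValueError("invalid protrusion length range")
        reach = self.body_radius_px + self.shell_thickness_px + hi
        if reach >= self.field_size_px / 2:
            raise ValueError("protrusion length exceeds the field")
        if hi + self.shell_thickness_px > self.neighbourhood_px:
            raise ValueError(
                "protrusions longer than the neighbourhood radius would violate truth-mask invariants"
            )
        if self.target is not None and self.target.onset_frame is not None:
            if not (0 <= self.target.onset_frame < self.n_frames):
                raise ValueError("target onset frame beyond n_frames")
        for role, f in self.channel_factors.items():
            f.validate()
            if role == "membrane_reference" and not f.is_uniform_marker():
                raise ValueError("membrane_reference factors must be uniform across regions")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


@dataclass
class FrameTruth:
    target: np.ndarray
    protrusion_contact: np.ndarray
    protrusion_noncontact: np.ndarray
    body_contact: np.ndarray
    body_noncontact: np.ndarray
    cluster_labels: np.ndarray


@dataclass
class SyntheticScene:
    params: SyntheticSceneParams
    masks: MembraneMasks  # static truth geometry (cell does not move)
    frames: list[FrameTruth]
    first_contact_frame: int | None
    resolved_factors: dict[str, RegionFactors]
    cluster_locations: list[str]
    channel_roles: dict[int, str]

    def membrane_masks(self, frame: int) -> MembraneMasks:  # noqa: ARG002
        return self.masks

    def signal_field(self, role: str, frame: int) -> np.ndarray:
        """Noiseless, unblurred analytic intensity field for one channel."""
        return _render_signal(self, role, frame)


def photon_scale_for_snr(snr: float, amplitude: float) -> float:
    """Photon scale giving sqrt(amplitude * scale) = snr at the membrane."""
    return snr**2 / amplitude


def suggested_config(params: SyntheticSceneParams, **overrides) -> "PipelineConfig":
    """Pipeline config with size parameters matched to the scene geometry.

    The dark-hole enhancement radius must exceed the cell radius for the
    enclosed interior to be retained, and the inner-body area floor must sit
    below the body disc area; everything else keeps its default.
    """
    from .image_model import PipelineConfig

    base = dict(
        holes_radius_px=int(params.body_radius_px + params.shell_thickness_px + 15),
        inner_body_min_area_px=int(0.5 * np.pi * params.body_radius_px**2),
        min_contact_px=2,
    )
    base.update(overrides)
    return PipelineConfig(**base)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _capsule_mask(
    shape: tuple[int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    half_width: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = p1 - p0
    L2 = float(d @ d)
    ty = yy - p0[0]
    tx = xx - p0[1]
    t = np.clip((ty * d[0] + tx * d[1]) / L2, 0.0, 1.0)
    dy = ty - t * d[0]
    dx = tx - t * d[1]
    return dy * dy + dx * dx <= half_width**2


def _build_geometry(params: SyntheticSceneParams) -> MembraneMasks:
    n = params.field_size_px
    centre = np.array([n / 2.0, n * 0.4])
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - centre[0], xx - centre[1])
    R, T = params.body_radius_px, params.shell_thickness_px
    inner = r <= R
    shell = (r > R) & (r <= R + T)

    rng = np.random.default_rng([params.seed, 1])
    lo, hi = params.protrusion_length_px
    min_sep = 2.0 * np.arcsin(
        min(1.0, (params.protrusion_width_px + 3.0) / (2.0 * R))
    )
    angles: list[float] = []
    for _ in range(10_000):
        if len(angles) == params.n_protrusions:
            break
        a = rng.uniform(0, 2 * np.pi)
        if all(
            min(abs(a - b), 2 * np.pi - abs(a - b)) > min_sep for b in angles
        ):
            angles.append(a)
    if len(angles) < params.n_protrusions:
        raise ValueError("could not place non-overlapping protrusions")

    protrusions = np.zeros((n, n), dtype=bool)
    outside_body = r > R + T
    for a in angles:
        u = np.array([np.sin(a), np.cos(a)])
        length = rng.uniform(lo, hi)
        p0 = centre + R * u
        p1 = centre + (R + T + length) * u
        protrusions |= _capsule_mask((n, n), p0, p1, params.protrusion_width_px / 2.0)
    protrusions &= outside_body  # shell pixels belong to the body membrane
    protrusions &= ~shell

    neighbourhood = dilate_mask(inner, params.neighbourhood_px)
    return MembraneMasks(
        inner_body=inner,
        neighbourhood=neighbourhood,
        protrusions=protrusions,
        body_membrane=shell,
        whole_membrane=protrusions | shell,
        valid=True,
    )


def _solve_protrusion_factor(masks: MembraneMasks, f: float) -> float:
    """Protrusion amplitude giving a true protrusion *enrichment* of f.

    Enrichment mixes the region into the whole-membrane mean, so a factor x
    against a factor-1 body satisfies x * A / (x * A_p + A_b) = f.
    """
    a_p = float(masks.protrusions.sum())
    a_b = float(masks.body_membrane.sum())
    a = a_p + a_b
    if f * a_p >= a:
        raise ValueError(
            f"planted enrichment {f} infeasible: protrusion area fraction too large"
        )
    return f * a_b / (a - f * a_p)


# ---------------------------------------------------------------------------
# target, clusters, rendering
# ---------------------------------------------------------------------------

def _target_boundary(params: SyntheticSceneParams, x_touch: int, frame: int) -> float:
    t = params.target
    assert t is not None and t.onset_frame is not None
    b = x_touch - t.overlap_px + 1 - t.speed_px_per_frame * (frame - t.onset_frame)
    centre_x = params.field_size_px * 0.4
    return max(b, centre_x)


def _grow_blob(
    shape: tuple[int, int], site: tuple[int, int], area: int
) -> np.ndarray:
    """Compact connected blob of exact pixel area around a site."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - site[0]) ** 2 + (xx - site[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:area]
    blob = np.zeros(shape, dtype=bool)
    blob.ravel()[order] = True
    return blob


def _plant_clusters(
    params: SyntheticSceneParams,
    masks: MembraneMasks,
    contact_membrane: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    """Label image of planted clusters plus their truth locations."""
    spec = params.cluster_spec
    assert spec is not None
    shape = masks.whole_membrane.shape
    if spec.location == "body":
        support = masks.body_membrane
    elif spec.location == "protrusion":
        support = masks.protrusions
    else:
        support = masks.whole_membrane
    if contact_membrane is not None:
        support = support & contact_membrane
    sites_pool = np.argwhere(support)
    if sites_pool.size == 0:
        return np.zeros(shape, dtype=np.int32), []

    areas = (
        list(spec.areas_px)
        if spec.areas_px is not None
        else [int(np.pi * spec.radius_px**2 + 0.5)] * spec.count
    )
    rng = np.random.default_rng([params.seed, 3])
    extents = [np.sqrt(a / np.pi) + 1 for a in areas]
    labels = np.zeros(shape, dtype=np.int32)
    chosen: list[np.ndarray] = []
    locations: list[str] = []
    attempts = 0
    while len(chosen) < len(areas) and attempts < 5000:
        attempts += 1
        k = len(chosen)
        site = sites_pool[rng.integers(len(sites_pool))]
        if any(
            np.hypot(*(site - c)) < extents[k] + extents[j] + 2
            for j, c in enumerate(chosen)
        ):
            continue
        blob = _grow_blob(shape, (int(site[0]), int(site[1])), areas[len(chosen)])
        labels[blob] = len(chosen) + 1
        loc = "protrusion" if masks.protrusions[site[0], site[1]] else "body"
        locations.append(loc)
        chosen.append(site)
    if len(chosen) < len(areas):
        raise ValueError("could not place non-overlapping clusters")
    return labels, locations


def _render_signal(scene: SyntheticScene, role: str, frame: int) -> np.ndarray:
    params = scene.params
    masks = scene.masks
    truth = scene.frames[frame]
    amp = params.membrane_amplitude

    if role == "target":
        sig = np.full(masks.whole_membrane.shape, 0.02 * amp)
        sig[truth.target] = amp
        return sig

    f = scene.resolved_factors[role]
    sig = np.full(masks.whole_membrane.shape, f.background * amp)
    sig[masks.inner_body] = f.cytoplasm * amp
    sig[truth.body_noncontact] = f.body * amp
    sig[truth.body_contact] = f.body_contact * amp
    sig[truth.protrusion_noncontact] = f.protrusion * amp
    sig[truth.protrusion_contact] = f.protrusion_contact * amp

    spec = params.cluster_spec
    if spec is not None and truth.cluster_labels.any():
        amp = spec.amplitude_map().get(role)
        if amp is not None:
            membrane_mean = sig[masks.whole_membrane].mean()
            sig[truth.cluster_labels > 0] = amp * membrane_mean
    return sig


def generate_scene(
    params: SyntheticSceneParams,
) -> tuple[SyntheticScene, FrameStack]:
    """Render a ground-truthed synthetic time lapse."""
    params.validate()
    masks = _build_geometry(params)

    resolved = {
        role: f.resolved() for role, f in params.channel_factors.items()
    }
    for role, f_target in params.protrusion_enrichment.items():
        x = _solve_protrusion_factor(masks, f_target)
        base = resolved[role]
        resolved[role] = RegionFactors(
            body=base.body,
            protrusion=x * base.body,
            body_contact=base.body_contact,
            protrusion_contact=x * base.body
            if params.channel_factors[role].protrusion_contact is None
            else base.protrusion_contact,
            cytoplasm=base.cytoplasm,
            background=base.background,
        )

    roles = [r for r in _CHANNEL_ORDER if r in resolved]
    if params.target is not None:
        roles.append("target")
    channel_roles = {i: r for i, r in enumerate(roles)}

    # per-frame target footprint and contact truth
    has_target = params.target is not None and params.target.onset_frame is not None
    x_touch = int(np.max(np.nonzero(masks.whole_membrane.any(axis=0))[0]))
    n = params.field_size_px
    xx = np.arange(n)[None, :]

    frames: list[FrameTruth] = []
    first_contact: int | None = None
    cluster_labels = np.zeros((n, n), dtype=np.int32)
    cluster_locations: list[str] = []
    scene = SyntheticScene(
        params=params,
        masks=masks,
        frames=frames,
        first_contact_frame=None,
        resolved_factors=resolved,
        cluster_locations=cluster_locations,
        channel_roles=channel_roles,
    )

    for fidx in range(params.n_frames):
        if has_target:
            boundary = _target_boundary(params, x_touch, fidx)
            target_fp = np.broadcast_to(xx >= boundary, (n, n)).copy()
        else:
            target_fp = np.zeros((n, n), dtype=bool)
        p_contact = masks.protrusions & target_fp
        b_contact = masks.body_membrane & target_fp
        in_contact = bool(p_contact.any() or b_contact.any())
        if in_contact and first_contact is None:
            first_contact = fidx

        if (
            params.cluster_spec is not None
            and not cluster_labels.any()
            and (
                (not has_target)
                or (
                    first_contact is not None
                    and fidx >= first_contact + params.cluster_spec.delay_frames
                )
            )
        ):
            contact_membrane = (p_contact | b_contact) if has_target else None
            cluster_labels, cluster_locations = _plant_clusters(
                params, masks, contact_membrane
            )
            scene.cluster_locations = cluster_locations

        frames.append(
            FrameTruth(
                target=target_fp,
                protrusion_contact=p_contact,
                protrusion_noncontact=masks.protrusions & ~p_contact,
                body_contact=b_contact,
                body_noncontact=masks.body_membrane & ~b_contact,
                cluster_labels=cluster_labels.copy(),
            )
        )

    scene.first_contact_frame = first_contact

    # render
    data = np.zeros((params.n_frames, len(roles), n, n), dtype=np.float64)
    for fidx in range(params.n_frames):
        for cidx, role in channel_roles.items():
            sig = _render_signal(scene, role, fidx)
            if params.psf_sigma_px > 0:
                sig = gaussian_blur(sig, params.psf_sigma_px)
            rng = np.random.default_rng([params.seed, 2, fidx, cidx])
            if params.photon_scale is not None:
                sig = rng.poisson(params.photon_scale * sig) / params.photon_scale
            if params.read_sigma > 0:
                sig = sig + rng.normal(0.0, params.read_sigma, size=sig.shape)
            data[fidx, cidx] = np.clip(sig, 0.0, None)

    stack = FrameStack(
        data=data,
        channel_roles=channel_roles,
        pixel_size_nm=params.pixel_size_nm,
        frame_interval_s=params.frame_interval_s,
    )
    return scene, stack


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------

def truth_metrics(scene: SyntheticScene) -> dict:
    """Expected metric values from truth masks and the analytic signal model.

    Computed directly from the unblurred, noiseless signal fields and the
    planted masks — no segmentation involved — for use as a recovery oracle.
    """
    from . import metrics as M

    masks = scene.masks
    out: dict = {"first_contact_frame": scene.first_contact_frame, "channels": {}}
    roles = [r for r in scene.channel_roles.values() if r != "target"]
    for role in roles:
        per_frame: list[dict] = []
        for fidx, truth in enumerate(scene.frames):
            sig = scene.signal_field(role, fidx)
            entry: dict = {
                "enrichment": {
                    "protrusion": M.enrichment(sig, masks.protrusions, masks.whole_membrane),
                    "body": M.enrichment(sig, masks.body_membrane, masks.whole_membrane),
                    "whole_membrane": 1.0,
                }
            }
            for region, c_mask, n_mask in (
                ("protrusion", truth.protrusion_contact, truth.protrusion_noncontact),
                ("body", truth.body_contact, truth.body_noncontact),
            ):
                if c_mask.any() and n_mask.any():
                    entry.setdefault("contact_relative_enrichment", {})[region] = (
                        M.contact_relative_enrichment(
                            sig, c_mask, n_mask, masks.whole_membrane
                        )
                    )
                    entry.setdefault("membrane_bound", {})[region] = M.membrane_bound(
                        sig, c_mask, n_mask, masks.whole_membrane
                    ).value
            per_frame.append(entry)
        out["channels"][role] = per_frame

    if "membrane_reference" in out["channels"]:
        for role in roles:
            if role == "membrane_reference":
                continue
            for fidx, entry in enumerate(out["channels"][role]):
                ref = out["channels"]["membrane_reference"][fidx]["enrichment"]
                entry["relative_enrichment"] = {
                    region: entry["enrichment"][region] / ref[region]
                    for region in ("protrusion", "body")
                }
    return out
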