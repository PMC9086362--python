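"""Synthetic negative-stain micrographs with exact ground truth.

Scenes emulate what matters to a threshold-based rod pipeline: dark
capsule-shaped rods (a rectangle with semicircular caps, default width
18 nm) on a brighter background with additive Gaussian noise and an
optional smooth intensity gradient, plus optional touching rod pairs and
non-rod debris. They deliberately do not model TEM image formation (CTF,
defocus, stain granularity beyond Gaussian noise).

Every rendered rod is recorded with its true length, width, orientation
and centre, so segmentation and measurement can be scored against exact
ground truth. End-to-end aggregates are rendered as a single capsule of
k x unit length and recorded with ``multimer_k = k``; staggered
side-by-side pairs are recorded as two rods flagged ``rogue_pair``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DEFAULT_PIXEL_SIZE_NM, Micrograph
from .report import LengthReport, build_report_from_lengths


class PlacementError(RuntimeError):
    """Requested objects cannot be placed in the image at the given gaps."""


@dataclass(frozen=True)
class NoiseModel:
    """Intensity model of the synthetic stain background.

    All values are in arbitrary detector units; only the contrast-to-noise
    ratio matters to the adaptive threshold. Defaults give a 10:1
    contrast-to-noise ratio and a mild large-scale illumination gradient
    (10% of background), the regime where negative-stain rods are
    unambiguous by eye.
    """

    background_level: float = 150.0
    object_contrast: float = 60.0
    gaussian_sd: float = 6.0
    gradient_amplitude: float = 15.0


@dataclass
class RodTruth:
    """Ground truth for one rendered rod (or end-to-end aggregate)."""

    true_length_nm: float
    true_width_nm: float
    orientation_deg: float
    center_px: tuple[float, float]      # (row, col)
    multimer_k: int = 1
    rogue_pair: bool = False
    truncated: bool = False


@dataclass
class DebrisTruth:
    """Ground truth for one elliptical debris blob."""

    center_px: tuple[float, float]
    semi_axes_nm: tuple[float, float]
    orientation_deg: float


@dataclass
class SyntheticScene:
    image: Micrograph
    rods: list[RodTruth]
    debris: list[DebrisTruth]
    noise_model: NoiseModel
    seed: int

    def ground_truth_mask(self) -> np.ndarray:
        """Exact rod footprint mask (pixel centres within a rod capsule)."""
        mask = np.zeros(self.image.shape, dtype=bool)
        ps = self.image.pixel_size_nm
        for rod in self.rods:
            p0, p1, hw = _spine_px(rod, ps)
            _paint_capsule(mask, p0, p1, hw, mode="mask")
        return mask


def _spine_px(rod: RodTruth, pixel_size_nm: float):
    """Spine segment endpoints (px) and half-width (px) of a capsule."""
    l_px = rod.true_length_nm / pixel_size_nm
    hw = (rod.true_width_nm / pixel_size_nm) / 2.0
    half_spine = max(l_px / 2.0 - hw, 0.0)
    theta = math.radians(rod.orientation_deg)
    d = np.array([math.sin(theta), math.cos(theta)])  # (drow, dcol)
    c = np.asarray(rod.center_px, dtype=float)
    return c - half_spine * d, c + half_spine * d, hw


def _paint_capsule(target: np.ndarray, p0, p1, halfwidth_px: float,
                   mode: str = "coverage", contrast: float = 0.0) -> None:
    """Stamp a capsule onto an image (subtract contrast) or a bool mask.

    ``mode='coverage'`` subtracts ``contrast`` weighted by an approximate
    per-pixel area coverage (linear ramp over one pixel at the boundary);
    ``mode='mask'`` ORs in pixels whose centres lie inside the capsule.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    pad = halfwidth_px + 2.0
    r0 = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, target.shape[0])
    c0 = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, target.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=float) + 0.5
    cols = np.arange(c0, c1, dtype=float) + 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    # distance from pixel centres to the spine segment
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    dr, dc = rr - p0[0], cc - p0[1]
    if seg_len2 > 0:
        t = np.clip((dr * seg[0] + dc * seg[1]) / seg_len2, 0.0, 1.0)
    else:
        t = 0.0
    dist = np.hypot(dr - t * seg[0], dc - t * seg[1])
    if mode == "mask":
        target[r0:r1, c0:c1] |= dist <= halfwidth_px
    else:
        coverage = np.clip(halfwidth_px + 0.5 - dist, 0.0, 1.0)
        target[r0:r1, c0:c1] -= contrast * coverage


def _paint_ellipse(target: np.ndarray, center, semi_axes_px, orientation_deg,
                   contrast: float) -> None:
    a, b = semi_axes_px
    pad = max(a, b) + 2.0
    r0 = max(int(np.floor(center[0] - pad)), 0)
    r1 = min(int(np.ceil(center[0] + pad)) + 1, target.shape[0])
    c0 = max(int(np.floor(center[1] - pad)), 0)
    c1 = min(int(np.ceil(center[1] + pad)) + 1, target.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=float) + 0.5 - center[0]
    cols = np.arange(c0, c1, dtype=float) + 0.5 - center[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    th = math.radians(orientation_deg)
    u = rr * math.cos(th) + cc * math.sin(th)
    v = -rr * math.sin(th) + cc * math.cos(th)
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # approximate 1-px anti-aliased edge in normalised radius
    edge = 1.0 / max(min(a, b), 1.0)
    coverage = np.clip((1.0 + edge - q) / edge, 0.0, 1.0) if edge > 0 else (q <= 1.0)
    target[r0:r1, c0:c1] -= contrast * np.clip(coverage, 0.0, 1.0)


def _rod_in_bounds(rod: RodTruth, shape, pixel_size_nm: float) -> bool:
    p0, p1, hw = _spine_px(rod, pixel_size_nm)
    lo = np.minimum(p0, p1) - hw
    hi = np.maximum(p0, p1) + hw
    return bool(lo.min() >= 0 and hi[0] <= shape[0] and hi[1] <= shape[1])


def render_custom_scene(
    rods: Sequence[RodTruth],
    debris: Sequence[DebrisTruth] = (),
    image_shape: tuple[int, int] = (1024, 1024),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    noise: NoiseModel | None = None,
    seed: int = 0,
    source_id: str | None = None,
) -> SyntheticScene:
    """Render an explicit list of rods/debris (no placement logic).

    Rods extending past the image border are clipped and flagged
    ``truncated`` in the ground truth.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    h, w = image_shape
    image = np.full(image_shape, noise.background_level, dtype=np.float64)

    if noise.gradient_amplitude:
        phi = rng.uniform(0, 2 * math.pi)
        phase = rng.uniform(0, 2 * math.pi)
        rr = np.arange(h, dtype=float)[:, None]
        cc = np.arange(w, dtype=float)[None, :]
        proj = (math.sin(phi) * rr + math.cos(phi) * cc) / max(h, w)
        image += noise.gradient_amplitude * np.cos(2 * math.pi * proj + phase)

    rods = list(rods)
    for rod in rods:
        rod.truncated = not _rod_in_bounds(rod, image_shape, pixel_size_nm)
        p0, p1, hw = _spine_px(rod, pixel_size_nm)
        _paint_capsule(image, p0, p1, hw, mode="coverage",
                       contrast=noise.object_contrast)
    for blob in debris:
        axes_px = (blob.semi_axes_nm[0] / pixel_size_nm,
                   blob.semi_axes_nm[1] / pixel_size_nm)
        _paint_ellipse(image, blob.center_px, axes_px, blob.orientation_deg,
                       noise.object_contrast)

    if noise.gaussian_sd:
        image += rng.normal(0.0, noise.gaussian_sd, size=image_shape)

    sid = source_id if source_id is not None else f"synthetic:seed={seed}"
    micrograph = Micrograph(pixels=image.astype(np.float32),
                            pixel_size_nm=pixel_size_nm, source_id=sid)
    return SyntheticScene(image=micrograph, rods=rods, debris=list(debris),
                          noise_model=noise, seed=seed)


def render_scene(
    lengths_nm: Sequence[float],
    width_nm: float = 18.0,
    image_shape: tuple[int, int] = (1024, 1024),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    noise: NoiseModel | None = None,
    min_gap_nm: float = 54.0,
    end_to_end: Sequence[tuple[float, int]] = (),
    side_by_side: Sequence[float] = (),
    n_debris: int = 0,
    seed: int = 0,
    source_id: str | None = None,
) -> SyntheticScene:
    """Place and render non-overlapping objects with guaranteed clearance.

    ``lengths_nm`` gives one isolated rod per entry; ``end_to_end`` entries
    ``(unit_length, k)`` each add one aggregate rendered as a k x unit
    capsule; ``side_by_side`` entries add a staggered touching pair (a
    "rogue" object). Placement uses a jittered grid whose cell size is set
    by the largest object plus ``min_gap_nm``, so footprints are pairwise
    separated by at least ``min_gap_nm``; a :class:`PlacementError` is
    raised when the image cannot hold the request.
    """
    if any(l <= 0 for l in lengths_nm) or width_nm <= 0:
        raise ValueError("rod lengths and width must be positive")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    ps = pixel_size_nm
    gap_px = min_gap_nm / ps

    # entity list: (kind, payload, footprint radius in px)
    entities: list[tuple[str, object, float]] = []
    for length in lengths_nm:
        r = 0.5 * math.hypot(length / ps, width_nm / ps)
        entities.append(("rod", float(length), r))
    for unit, k in end_to_end:
        if k < 1 or unit <= 0:
            raise ValueError("end_to_end entries must have unit > 0 and k >= 1")
        r = 0.5 * math.hypot(k * unit / ps, width_nm / ps)
        entities.append(("multimer", (float(unit), int(k)), r))
    for length in side_by_side:
        r = 0.5 * math.hypot(1.4 * length / ps, 2.0 * width_nm / ps)
        entities.append(("pair", float(length), r))
    debris_axes = []
    for _ in range(n_debris):
        if rng.random() < 0.5:  # small blob: fails the area filter
            axes = tuple(sorted(rng.uniform(5.0, 8.0, size=2), reverse=True))
        else:                   # wide blob: fails the minor-axis filter
            axes = tuple(sorted(rng.uniform(25.0, 35.0, size=2), reverse=True))
        debris_axes.append(axes)
        entities.append(("debris", axes, axes[0] / ps))

    if not entities:
        return render_custom_scene([], [], image_shape, ps, noise, seed, source_id)

    max_r = max(r for _, _, r in entities)
    cell = 2 * max_r + gap_px
    n_rows = int(image_shape[0] // cell)
    n_cols = int(image_shape[1] // cell)
    if n_rows * n_cols < len(entities):
        raise PlacementError(
            f"cannot place {len(entities)} objects of footprint radius "
            f"<= {max_r:.0f} px with {min_gap_nm} nm gaps in a "
            f"{image_shape[0]}x{image_shape[1]} image "
            f"(capacity {n_rows * n_cols})"
        )
    cell_h = image_shape[0] / n_rows
    cell_w = image_shape[1] / n_cols
    cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
    order = rng.permutation(len(cells))

    rods: list[RodTruth] = []
    debris: list[DebrisTruth] = []
    for (kind, payload, radius), idx in zip(entities, order):
        i, j = cells[idx]
        jit = min(cell_h, cell_w) / 2.0 - radius - gap_px / 2.0
        jit = max(jit, 0.0)
        center = (
            (i + 0.5) * cell_h + rng.uniform(-jit, jit),
            (j + 0.5) * cell_w + rng.uniform(-jit, jit),
        )
        theta = rng.uniform(0.0, 180.0)
        if kind == "rod":
            rods.append(RodTruth(payload, width_nm, theta, center))
        elif kind == "multimer":
            unit, k = payload
            rods.append(RodTruth(k * unit, width_nm, theta, center, multimer_k=k))
        elif kind == "pair":
            length = payload
            th = math.radians(theta)
            axis = np.array([math.sin(th), math.cos(th)])
            normal = np.array([math.cos(th), -math.sin(th)])
            off_ax = 0.2 * length / ps          # longitudinal stagger
            off_no = 0.45 * width_nm / ps       # lateral: centres 0.9 widths apart
            c = np.asarray(center)
            for s in (+1, -1):
                pc = c + s * (off_ax * axis + off_no * normal)
                rods.append(RodTruth(length, width_nm, theta,
                                     (float(pc[0]), float(pc[1])),
                                     rogue_pair=True))
        else:  # debris
            debris.append(DebrisTruth(center, payload, theta))

    return render_custom_scene(rods, debris, image_shape, ps, noise,
                               seed, source_id)


def scene_ground_truth_report(
    scene: SyntheticScene, bin_width_nm: float = 10.0
) -> LengthReport:
    """The report an ideal pipeline would produce (true lengths, 10-nm bins)."""
    lengths = [rod.true_length_nm for rod in scene.rods]
    return build_report_from_lengths(lengths, bin_width_nm)
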