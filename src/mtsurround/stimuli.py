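"""Procedural stimulus generation with ground-truth masks.

All stimuli are grayscale frame sequences (intensities in [0, 1]) rendered
deterministically on a pixel grid; there is no randomness anywhere.  Bars
are rectangles rendered by pixel coverage (a pixel's intensity is the
fraction of its area inside the continuous rectangle, estimated on a 4x4
subgrid), so sub-pixel translation produces genuinely smooth motion
instead of occasional whole-pixel jumps; boolean masks use half-coverage.

Coordinates: frames are indexed ``(row, col)``.  Physical coordinates put
the origin at the frame center with x increasing with column and y
increasing *upward* (decreasing row), so a direction of 0 deg is rightward
motion on screen and 90 deg is upward.  Direction channel ``i`` of the model
prefers motion at ``45*i`` degrees in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .config import ModelParams

__all__ = ["FrameSequence", "StimulusSpec", "GroundTruth", "GeometryError",
           "crossing_bars", "occluded_plaid", "single_bar", "grating",
           "plaid_spec", "direction_channel"]


def plaid_spec(**overrides) -> "StimulusSpec":
    """Canonical occluded-plaid geometry.

    Longer bars on a wider frame than the two-bar default, so that the
    visible arms between the junction and the static occluders are long
    enough to (i) read as extended contours to the end-stopping circuit
    and (ii) keep their outer stretches clear of the other bar's
    long-range inhibition; the occluders still cover the full excursion
    of the hidden intrinsic terminators.
    """
    kwargs = dict(kind="occluded_plaid", bar_length=18.0, n_frames=160,
                  height=80, width=80, occluder_size=6.0)
    kwargs.update(overrides)
    return StimulusSpec(**kwargs)


class GeometryError(ValueError):
    """Stimulus geometry impossible to render (e.g., bar leaves the frame)."""


@dataclass
class FrameSequence:
    """A stimulus: ``frames`` of shape (T, H, W) with intensities in [0, 1]."""

    frames: np.ndarray
    deg_per_pixel: float
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        T, H, W = self.frames.shape
        if T < 2:
            raise ValueError(f"need at least 2 frames, got {T}")
        if H < 32 or W < 32:
            raise ValueError(f"frame must be at least 32x32, got {H}x{W}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"intensities outside [0, 1]: min={lo}, max={hi}")

    @property
    def shape(self):
        return self.frames.shape


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of one stimulus.

    Angles are in degrees; lengths in degrees of visual angle; ``speed`` in
    degrees per time unit; ``directions`` are translation directions, one
    per bar.
    """

    kind: Literal["crossing_bars", "occluded_plaid", "single_bar", "grating"]
    orientations: Sequence[float] = (135.0, 45.0)
    directions: Sequence[float] = (0.0, 180.0)
    speed: float = 2.5
    contrasts: Sequence[float] = (1.0, 1.0)
    bar_length: float = 10.0
    bar_width: float = 0.5
    occluder_size: float = 6.0
    occluder_intensity: float = 0.35
    n_frames: int = 280
    height: int = 64
    width: int = 64
    terminator_radius: float = 0.5

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError(f"speed must be positive, got {self.speed}")
        for c in self.contrasts:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"contrast {c} outside [0, 1]")
        if self.kind in ("crossing_bars", "occluded_plaid"):
            o = [x % 180.0 for x in self.orientations[:2]]
            if abs(o[0] - o[1]) < 1e-9:
                raise ValueError("two-bar stimuli need distinct orientations")


@dataclass
class GroundTruth:
    """Per-frame boolean masks plus the true direction channel of each bar.

    ``on_bar[b][t]`` marks the (possibly occluded) body of bar ``b``;
    ``intrinsic`` / ``extrinsic`` mark true bar end-points and the crossing
    junction; ``mid_edge`` marks on-bar pixels at least 3 units away from
    any terminator.  Intrinsic and extrinsic masks are disjoint.
    """

    on_bar: list[np.ndarray]
    intrinsic: np.ndarray
    extrinsic: np.ndarray
    mid_edge: np.ndarray
    true_channels: list[int]
    junction_rc: np.ndarray | None = None  # (T, 2) row/col of the junction


def direction_channel(angle_deg: float, n: int = 8) -> int:
    """Map a motion direction in degrees to the nearest of ``n`` channels."""
    return round((angle_deg % 360.0) / (360.0 / n)) % n


# --------------------------------------------------------------------------
# geometry helpers

def _grid(H: int, W: int, dpp: float):
    """Physical (x, y) coordinates of pixel centers; y increases upward."""
    cols = (np.arange(W) - (W - 1) / 2.0) * dpp
    rows = ((H - 1) / 2.0 - np.arange(H)) * dpp
    x = np.broadcast_to(cols[None, :], (H, W))
    y = np.broadcast_to(rows[:, None], (H, W))
    return x, y


_SUBGRID = 4  # supersampling factor for coverage rendering


def _bar_coverage(x, y, dpp, center, orientation_deg, length, width):
    """Fractional pixel coverage of a rectangle, on a 4x4 subpixel grid."""
    th = np.deg2rad(orientation_deg)
    ux, uy = np.cos(th), np.sin(th)          # long axis
    n = _SUBGRID
    offs = (np.arange(n) + 0.5) / n - 0.5    # subpixel offsets in pixels
    cov = np.zeros(x.shape)
    for oy in offs:
        for ox in offs:
            dx = x + ox * dpp - center[0]
            dy = y - oy * dpp - center[1]
            along = dx * ux + dy * uy
            across = -dx * uy + dy * ux
            cov += ((np.abs(along) <= length / 2.0)
                    & (np.abs(across) <= width / 2.0))
    return cov / (n * n)


def _disk_mask(x, y, center, radius):
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2


def _xy_to_rc(px, py, H, W, dpp):
    """Physical point -> nearest (row, col)."""
    c = int(round(px / dpp + (W - 1) / 2.0))
    r = int(round((H - 1) / 2.0 - py / dpp))
    return r, c


def _render_bars(spec: StimulusSpec, p: ModelParams, n_bars: int):
    """Render bar frames and raw per-bar masks; raise if a bar exits."""
    H, W, T = spec.height, spec.width, spec.n_frames
    dpp = p.deg_per_pixel
    x, y = _grid(H, W, dpp)
    half_x = (W - 1) / 2.0 * dpp
    half_y = (H - 1) / 2.0 * dpp
    duration = (T - 1) * p.dt

    frames = np.zeros((T, H, W))
    covs = [np.zeros((T, H, W)) for _ in range(n_bars)]
    masks = [np.zeros((T, H, W), dtype=bool) for _ in range(n_bars)]
    endpoints = [[] for _ in range(n_bars)]  # per bar: list over t of 2 endpoints
    centers_t = [[] for _ in range(n_bars)]

    for b in range(n_bars):
        th = np.deg2rad(spec.directions[b])
        vx, vy = spec.speed * np.cos(th), spec.speed * np.sin(th)
        # center the excursion on the frame
        cx0, cy0 = -vx * duration / 2.0, -vy * duration / 2.0
        oth = np.deg2rad(spec.orientations[b])
        ux, uy = np.cos(oth), np.sin(oth)
        for t in range(T):
            cx, cy = cx0 + vx * t * p.dt, cy0 + vy * t * p.dt
            e1 = (cx + ux * spec.bar_length / 2.0, cy + uy * spec.bar_length / 2.0)
            e2 = (cx - ux * spec.bar_length / 2.0, cy - uy * spec.bar_length / 2.0)
            for ex, ey in (e1, e2):
                if abs(ex) > half_x or abs(ey) > half_y:
                    raise GeometryError(
                        f"bar {b} end-point leaves the frame at frame {t}")
            cov = _bar_coverage(x, y, dpp, (cx, cy), spec.orientations[b],
                                spec.bar_length, spec.bar_width)
            covs[b][t] = cov
            masks[b][t] = cov >= 0.5
            endpoints[b].append((e1, e2))
            centers_t[b].append((cx, cy))

    # over-compositing: brighter bar drawn on top at overlaps
    order = np.argsort([spec.contrasts[b] for b in range(n_bars)])[::-1]
    for t in range(T):
        img = np.zeros((H, W))
        remaining = np.ones((H, W))
        for b in order:  # brightest first
            img += remaining * covs[b][t] * spec.contrasts[b]
            remaining *= 1.0 - covs[b][t]
        frames[t] = np.clip(img, 0.0, 1.0)
    return frames, masks, endpoints, centers_t, (x, y)


def _junction_track(spec: StimulusSpec, p: ModelParams, centers_t):
    """Intersection point of the two bar axes, per frame."""
    pts = []
    th0 = np.deg2rad(spec.orientations[0])
    th1 = np.deg2rad(spec.orientations[1])
    u0 = np.array([np.cos(th0), np.sin(th0)])
    u1 = np.array([np.cos(th1), np.sin(th1)])
    A = np.stack([u0, -u1], axis=1)
    for t in range(len(centers_t[0])):
        c0 = np.array(centers_t[0][t])
        c1 = np.array(centers_t[1][t])
        s = np.linalg.solve(A, c1 - c0)
        pts.append(c0 + s[0] * u0)
    return np.array(pts)


def _terminator_masks(spec, p, masks, endpoints, grid, junction=None,
                      occluded=None):
    """Build intrinsic/extrinsic/mid-edge masks for a bar stimulus."""
    x, y = grid
    T = masks[0].shape[0]
    H, W = masks[0].shape[1:]
    rad = spec.terminator_radius
    intr = np.zeros((T, H, W), dtype=bool)
    extr = np.zeros((T, H, W), dtype=bool)
    union = np.zeros((T, H, W), dtype=bool)
    for b, m in enumerate(masks):
        union |= m
        for t in range(T):
            for e in endpoints[b][t]:
                intr[t] |= _disk_mask(x, y, e, rad) & m[t]
    if junction is not None:
        for t in range(T):
            extr[t] = _disk_mask(x, y, tuple(junction[t]), rad) & union[t]
    intr &= ~extr
    if occluded is not None:
        intr &= ~occluded
    # mid-edge: on-bar, >= 3 units from any terminator
    from scipy.ndimage import binary_dilation
    se = np.zeros((5, 5), dtype=bool)
    rr, cc = np.mgrid[-2:3, -2:3]
    se[rr ** 2 + cc ** 2 <= 2.9 ** 2] = True  # radius-<3 neighbourhood
    mid = np.zeros_like(union)
    for t in range(T):
        near = binary_dilation(intr[t] | extr[t], structure=se, iterations=1)
        mid[t] = union[t] & ~near
    return intr, extr, mid


# --------------------------------------------------------------------------
# public generators

def crossing_bars(spec: StimulusSpec, p: ModelParams):
    """Two bright bars on a dark background translating in opposite
    directions; their crossing junction is an extrinsic terminator.

    With equal contrasts this is the equal-contrast two-bar configuration;
    with unequal contrasts the brighter bar is drawn on top at the junction
    (it reads as sliding in front).

    Returns ``(FrameSequence, GroundTruth)``.
    """
    if spec.kind != "crossing_bars":
        raise ValueError(f"spec.kind must be 'crossing_bars', got {spec.kind!r}")
    frames, masks, endpoints, centers_t, grid = _render_bars(spec, p, 2)
    junction = _junction_track(spec, p, centers_t)
    intr, extr, mid = _terminator_masks(spec, p, masks, endpoints, grid,
                                        junction=junction)
    H, W = spec.height, spec.width
    jr = np.array([_xy_to_rc(px, py, H, W, p.deg_per_pixel) for px, py in junction])
    gt = GroundTruth(
        on_bar=masks, intrinsic=intr, extrinsic=extr, mid_edge=mid,
        true_channels=[direction_channel(d, p.N) for d in spec.directions[:2]],
        junction_rc=jr)
    return FrameSequence(frames, p.deg_per_pixel, p.dt), gt


def occluded_plaid(spec: StimulusSpec, p: ModelParams):
    """Crossing bars with static occluders hiding all intrinsic terminators.

    The occluders take ``spec.occluder_intensity`` (background by default,
    so the hidden terminators are invisible); the ground-truth intrinsic
    mask is empty and the visible junction remains the only terminator.
    """
    if spec.kind != "occluded_plaid":
        raise ValueError(f"spec.kind must be 'occluded_plaid', got {spec.kind!r}")
    frames, masks, endpoints, centers_t, grid = _render_bars(spec, p, 2)
    x, y = grid
    T = spec.n_frames

    # static square occluders centered on each end-point's mean position
    occ = np.zeros((spec.height, spec.width), dtype=bool)
    half = spec.occluder_size / 2.0
    margin = spec.terminator_radius + spec.bar_width
    for b in range(2):
        for e_idx in range(2):
            track = np.array([endpoints[b][t][e_idx] for t in range(T)])
            cx, cy = track.mean(axis=0)
            box = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)
            need = ((np.abs(track[:, 0] - cx) + margin > half)
                    | (np.abs(track[:, 1] - cy) + margin > half))
            if need.any():
                raise GeometryError(
                    f"occluder (size {spec.occluder_size} deg) too small for "
                    f"the terminator excursion of bar {b}")
            occ |= box

    frames[:, occ] = spec.occluder_intensity
    occ_t = np.broadcast_to(occ, frames.shape)
    junction = _junction_track(spec, p, centers_t)
    masks = [m & ~occ for m in masks]
    intr, extr, mid = _terminator_masks(spec, p, masks, endpoints, grid,
                                        junction=junction, occluded=occ_t)
    intr[:] = False  # all intrinsic terminators are hidden by construction
    H, W = spec.height, spec.width
    jr = np.array([_xy_to_rc(px, py, H, W, p.deg_per_pixel) for px, py in junction])
    gt = GroundTruth(
        on_bar=masks, intrinsic=intr, extrinsic=extr, mid_edge=mid,
        true_channels=[direction_channel(d, p.N) for d in spec.directions[:2]],
        junction_rc=jr)
    return FrameSequence(frames, p.deg_per_pixel, p.dt), gt


def single_bar(spec: StimulusSpec, p: ModelParams):
    """One translating bar with two intrinsic terminators (no junction)."""
    if spec.kind != "single_bar":
        raise ValueError(f"spec.kind must be 'single_bar', got {spec.kind!r}")
    frames, masks, endpoints, centers_t, grid = _render_bars(spec, p, 1)
    intr, extr, mid = _terminator_masks(spec, p, masks, endpoints, grid)
    gt = GroundTruth(
        on_bar=masks, intrinsic=intr, extrinsic=extr, mid_edge=mid,
        true_channels=[direction_channel(spec.directions[0], p.N)])
    return FrameSequence(frames, p.deg_per_pixel, p.dt), gt


def grating(spec: StimulusSpec, p: ModelParams) -> FrameSequence:
    """Full-field sinusoidal grating at spatial frequency ``p.f`` drifting
    rigidly in ``spec.directions[0]`` at ``spec.speed`` deg per time unit."""
    if spec.kind != "grating":
        raise ValueError(f"spec.kind must be 'grating', got {spec.kind!r}")
    H, W, T = spec.height, spec.width, spec.n_frames
    x, y = _grid(H, W, p.deg_per_pixel)
    th = np.deg2rad(spec.directions[0])
    u = x * np.cos(th) + y * np.sin(th)
    c = spec.contrasts[0]
    t = np.arange(T)[:, None, None] * p.dt
    phase = 2.0 * np.pi * p.f * (u[None] - spec.speed * t)
    frames = 0.5 + 0.5 * c * np.sin(phase)
    return FrameSequence(frames, p.deg_per_pixel, p.dt)
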