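"""Complex-V1 direction-selective responses via spatiotemporal motion energy.

The front end is the classic opponent motion-energy construction: quadrature
Gabor pairs (even/odd phase) at each of the 8 preferred directions, each
filtered in time by a fast (order 6) and a slow (order 9) multi-stage
low-pass kernel whose difference in delay provides the temporal quadrature.
Per direction,

    E_theta = (even*g_fast - odd*g_slow)^2 + (odd*g_fast + even*g_slow)^2,

followed by opponent subtraction ``E_theta - E_{theta+180}``, half-wave
rectification, and normalization by a calibration constant frozen from the
response to a full-contrast drifting grating at the optimal spatiotemporal
frequency, so that activities live in [0, 1] and downstream thresholds are
meaningful.

Conventions: direction channel ``i`` prefers motion at ``45*i`` degrees
(0 = rightward, 90 = upward on screen).  The Gabor carrier runs along the
direction of motion (perpendicular to the preferred edge).  Spatial
convolution is zero-padded; a border ring of half the spatial-kernel width
is unreliable and its width is exposed as :func:`border_width`.  Temporal
filtering is causal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .config import ModelParams
from .stimuli import FrameSequence

__all__ = ["TemporalKernel", "GaborKernel", "temporal_kernel", "gabor_bank",
           "complex_v1_response", "raw_motion_energy", "border_width",
           "calibration_constant"]


# --------------------------------------------------------------------------
# temporal kernels

@dataclass(frozen=True)
class TemporalKernel:
    """Sampled multi-stage low-pass filter ``g_n`` (biphasic for n >= 1)."""

    n: int
    tau_g: float
    dt: float
    weights: np.ndarray  # g_n evaluated at t = 0, dt, ..., t_max


def _g(n: int, tau: float, t: np.ndarray) -> np.ndarray:
    s = t / tau
    return s ** n * np.exp(-s) * (1.0 / math.factorial(n)
                                  - s ** 2 / math.factorial(n + 2))


def temporal_kernel(n: int, tau_g: float, dt: float,
                    t_max: float = 0.5) -> TemporalKernel:
    """Sample the order-``n`` temporal kernel on ``t = 0, dt, ..., t_max``.

    Raises a ``ValueError`` if the window is too small to contain the
    biphasic lobe (the kernel must decay below 1e-6 of its peak magnitude
    by ``t_max``, and must have changed sign).
    """
    if n < 1:
        raise ValueError(f"kernel order must be >= 1, got {n}")
    if tau_g <= 0 or dt <= 0:
        raise ValueError("tau_g and dt must be positive")
    t = np.arange(0.0, t_max + dt / 2, dt)
    w = _g(n, tau_g, t)
    peak = np.abs(w).max()
    if peak == 0.0 or np.abs(w[-1]) > 1e-6 * peak or w[-1] >= 0 or w.max() <= 0:
        raise ValueError(
            f"t_max={t_max} too small for the biphasic lobe of g_{n} "
            f"(tau_g={tau_g})")
    return TemporalKernel(n=n, tau_g=tau_g, dt=dt, weights=w)


# --------------------------------------------------------------------------
# spatial Gabor bank

@dataclass(frozen=True)
class GaborKernel:
    """One phase of a quadrature Gabor pair for a direction channel."""

    direction: float            # preferred motion direction, degrees
    phase: Literal["even", "odd"]
    weights: np.ndarray         # (K, K), row 0 at the top of the patch
    f: float
    sigma_x: float
    sigma_y: float


def _gabor_grid(p: ModelParams, radius_px: int):
    """Patch coordinates in degrees, y increasing upward."""
    r = np.arange(-radius_px, radius_px + 1)
    x = r[None, :] * p.deg_per_pixel
    y = -r[:, None] * p.deg_per_pixel
    return x, y


def gabor_radius(p: ModelParams) -> int:
    """Half-width of the Gabor patch in pixels (4 SD support)."""
    return int(np.ceil(4.0 * max(p.sigma_x, p.sigma_y) / p.deg_per_pixel))


def border_width(p: ModelParams) -> int:
    """Width of the unreliable zero-padded border ring, in pixels."""
    return gabor_radius(p)


def gabor_bank(p: ModelParams) -> list[GaborKernel]:
    """Even/odd Gabor pairs for all ``p.N`` directions.

    The carrier runs along the motion direction; the odd kernel is
    antisymmetric (sums to zero on the symmetric grid) and leads the even
    kernel in the direction of motion.
    """
    radius = gabor_radius(p)
    x, y = _gabor_grid(p, radius)
    out: list[GaborKernel] = []
    for theta in p.directions:
        th = np.deg2rad(theta)
        u = x * np.cos(th) + y * np.sin(th)    # along motion
        w = -x * np.sin(th) + y * np.cos(th)   # along the preferred edge
        env = np.exp(-(u ** 2 / (2 * p.sigma_x ** 2)
                       + w ** 2 / (2 * p.sigma_y ** 2)))
        carrier = 2.0 * np.pi * p.f * u
        for phase, kern in (("even", env * np.cos(carrier)),
                            ("odd", env * np.sin(carrier))):
            out.append(GaborKernel(direction=theta, phase=phase,
                                   weights=kern, f=p.f,
                                   sigma_x=p.sigma_x, sigma_y=p.sigma_y))
    return out


# --------------------------------------------------------------------------
# motion energy

def _spatial_responses(frames: np.ndarray, p: ModelParams):
    """Even/odd spatial responses for the 4 distinct carrier axes.

    Directions theta and theta+180 share kernels up to the sign of the odd
    phase (even kernels are centrally symmetric, odd antisymmetric), so only
    ``N // 2`` convolution pairs are computed.
    """
    bank = gabor_bank(p)
    by_key = {(k.direction, k.phase): k.weights for k in bank}
    half = p.N // 2
    even = np.empty((half,) + frames.shape)
    odd = np.empty_like(even)
    for i in range(half):
        theta = p.directions[i]
        # correlation: flip the kernel for fftconvolve
        ke = by_key[(theta, "even")][::-1, ::-1]
        ko = by_key[(theta, "odd")][::-1, ::-1]
        even[i] = fftconvolve(frames, ke[None], mode="same", axes=(1, 2))
        odd[i] = fftconvolve(frames, ko[None], mode="same", axes=(1, 2))
    return even, odd


def raw_motion_energy(frames: np.ndarray, p: ModelParams,
                      t_max: float = 0.5) -> np.ndarray:
    """Unnormalized opponent motion energy, shape (T, H, W, N)."""
    frames = np.asarray(frames, dtype=np.float64)
    even, odd = _spatial_responses(frames, p)
    gf = temporal_kernel(p.n_fast, p.tau_g, p.dt, t_max).weights
    gs = temporal_kernel(p.n_slow, p.tau_g, p.dt, t_max).weights

    half = p.N // 2
    T, H, W = frames.shape
    E = np.empty((T, H, W, p.N))
    for i in range(half):
        ef = lfilter(gf, [1.0], even[i], axis=0)
        es = lfilter(gs, [1.0], even[i], axis=0)
        of = lfilter(gf, [1.0], odd[i], axis=0)
        os_ = lfilter(gs, [1.0], odd[i], axis=0)
        E[..., i] = (ef - os_) ** 2 + (of + es) ** 2
        # theta + 180: odd responses change sign
        E[..., i + half] = (ef + os_) ** 2 + (-of + es) ** 2
    opp = np.empty_like(E)
    for i in range(p.N):
        opp[..., i] = E[..., i] - E[..., (i + p.N // 2) % p.N]
    return np.maximum(opp, 0.0)


_CALIBRATION_CACHE: dict[tuple, float] = {}


def _calibration_key(p: ModelParams) -> tuple:
    return (p.f, p.sigma_x, p.sigma_y, p.n_fast, p.n_slow, p.tau_g, p.dt,
            p.deg_per_pixel, p.N)


#: reference stimulus for normalization: a full-contrast bar at the default
#: geometry and drift speed (deg per time unit)
CALIBRATION_SPEED = 2.5


def calibration_constant(p: ModelParams) -> float:
    """Peak raw opponent energy of a full-contrast translating bar.

    The normalization reference is the model's canonical *unambiguous*
    signal: the peak true-direction-channel response at the intrinsic
    terminators of a unit-contrast bar of the default geometry drifting
    normal to one of its edges.  Anchoring the scale to the terminator
    response puts the aperture-resolving corner signals at full scale
    (where the end-stopped stage and the MT thresholds need them), while
    the much stronger ambiguous extended-edge responses saturate at 1 —
    which also renders the complex-V1 stage contrast-insensitive for
    extended contours, as this cell class is.  Measured once per parameter
    set and cached.
    """
    key = _calibration_key(p)
    if key not in _CALIBRATION_CACHE:
        from .stimuli import StimulusSpec, single_bar, direction_channel
        n_frames = 60
        spec = StimulusSpec(kind="single_bar", orientations=(45.0,),
                            directions=(0.0,), speed=CALIBRATION_SPEED,
                            contrasts=(1.0,), n_frames=n_frames,
                            height=64, width=64)
        seq, gt = single_bar(spec, p)
        raw = raw_motion_energy(seq.frames, p)
        ch = direction_channel(spec.directions[0], p.N)
        best = 0.0
        for t in range(n_frames // 2, n_frames):
            vals = raw[t][gt.intrinsic[t], ch]
            if vals.size:
                best = max(best, float(vals.max()))
        if best <= 0:
            raise RuntimeError("motion-energy calibration produced no response")
        _CALIBRATION_CACHE[key] = best
    return _CALIBRATION_CACHE[key]


def complex_v1_response(frames: FrameSequence | np.ndarray, p: ModelParams,
                        t_max: float = 0.5,
                        threshold: bool = True) -> np.ndarray:
    """Normalized complex-V1 activity maps, shape (T, H, W, N), in [0, 1].

    After normalization the activity threshold ``rho_cx`` is applied to the
    output (sub-threshold responses are silenced).  This keeps the channel
    maps sparse: the Gabor envelope smears energy several pixels beyond a
    contour, and without the threshold that halo seeds spurious activity in
    the low-contrast (facilitatory-surround) zone flanking every edge.
    ``frames`` may be a :class:`~mtsurround.stimuli.FrameSequence` or a raw
    (T, H, W) array of intensities.
    """
    arr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    raw = raw_motion_energy(arr, p, t_max)
    v = np.clip(raw / calibration_constant(p), 0.0, 1.0)
    if threshold:
        v = np.where(v > p.rho_cx, v, 0.0)
    return v
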