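"""End-stopped V1 units: shunting dynamics with thresholded lateral inhibition.

A unit is driven by the co-located, co-tuned complex-V1 response and
inhibited by its like-tuned neighbours, so that activity survives only
where the contour ends (terminators) and is crushed along extended edges
where many neighbours are active:

    dv/dt = (1 - v) * Gescx1 * v_cx  -  v * (tau_es + Gescx2 * Gamma),

where ``Gamma`` is a Gaussian-weighted sum of neighbouring complex-V1
activities, each neighbour contributing only if it individually exceeds the
threshold ``rho_cx``.  The lateral window is an annulus: discretized
Gaussian weights with a zeroed central core sized to the motion-energy
point spread (see :func:`lateral_weights`), so inhibition is driven by
same-channel activity *beyond* the local feature.  An extended edge keeps
driving the ring and is crushed; a terminator blob, which the front end
smears over the core but not beyond it, is not.  The
threshold is applied per neighbour, which keeps the inhibition field
smooth.  The shunting form keeps v in [0, 1]; the forward-Euler update
additionally clips.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import fftconvolve

from .config import ModelParams

__all__ = ["lateral_weights", "inhibition_field", "endstopped_step",
           "endstopped_equilibrium", "endstopped_response"]

def lateral_weights(p: ModelParams | None = None,
                    inner: int | None = None,
                    outer: int | None = None,
                    sd: float | None = None) -> np.ndarray:
    """Inhibitory connectivity matrix ``mu``: an annular discretized
    Gaussian.

    Weights cover offsets ``-outer..outer`` with the central
    ``-inner..inner`` square zeroed.  The annular form is what makes the
    units end-stopped: same-channel activity *beyond* the local feature
    (an edge continuing past the core) inhibits, while a compact
    terminator blob does not inhibit itself.  Because the motion-energy
    stage smears even a point feature over the Gabor support, the core
    must cover that point spread: by default ``inner`` is the Gabor patch
    radius, ``outer`` twice that, and the Gaussian SD three quarters of
    the core radius.
    """
    if inner is None:
        from .v1_motion_energy import gabor_radius
        inner = gabor_radius(p) if p is not None else 8
    if outer is None:
        outer = 2 * inner
    if sd is None:
        sd = 0.75 * inner
    r = np.arange(-outer, outer + 1)
    d2 = r[:, None] ** 2 + r[None, :] ** 2
    mu = np.exp(-d2 / (2.0 * sd ** 2))
    c = outer
    mu[c - inner:c + inner + 1, c - inner:c + inner + 1] = 0.0
    return mu


def inhibition_field(v_cx: np.ndarray, p: ModelParams,
                     mu: np.ndarray | None = None) -> np.ndarray:
    """Lateral inhibition ``Gamma`` onto each end-stopped unit.

    ``v_cx`` has shape (..., H, W, N); neighbours below ``rho_cx`` do not
    contribute, and out-of-frame neighbours contribute zero.
    """
    if mu is None:
        mu = lateral_weights(p)
    v = np.asarray(v_cx, dtype=np.float64)
    masked = np.where(v > p.rho_cx, v, 0.0)
    # mu is centrally symmetric, so convolution == correlation
    kern = mu.reshape((1,) * (v.ndim - 3) + mu.shape + (1,))
    return fftconvolve(masked, kern, mode="same",
                       axes=(v.ndim - 3, v.ndim - 2))


def endstopped_step(v_es: np.ndarray, v_cx: np.ndarray, p: ModelParams,
                    gamma: np.ndarray | None = None) -> np.ndarray:
    """One forward-Euler update of the shunting dynamics, clipped to [0, 1].

    Emits a stability warning if the unclipped update leaves [0, 1] by more
    than 0.1 anywhere (dt too large for the inhibition strength).
    """
    if gamma is None:
        gamma = inhibition_field(v_cx, p)
    rhs = (1.0 - v_es) * p.Gescx1 * v_cx - v_es * (p.tau_es + p.Gescx2 * gamma)
    new = v_es + p.dt * rhs
    if float(new.min(initial=0.0)) < -0.1 or float(new.max(initial=0.0)) > 1.1:
        warnings.warn("end-stopped Euler update overshoots [0,1] by > 0.1; "
                      "dt is too large for stability", RuntimeWarning)
    return np.clip(new, 0.0, 1.0)


def endstopped_equilibrium(v_cx, gamma, p: ModelParams):
    """Closed-form fixed point v* = G1 v_cx / (G1 v_cx + tau_es + G2 Gamma)."""
    drive = p.Gescx1 * np.asarray(v_cx, dtype=np.float64)
    return drive / (drive + p.tau_es + p.Gescx2 * np.asarray(gamma))


def endstopped_response(v_cx_t: np.ndarray, p: ModelParams,
                        gamma_t: np.ndarray | None = None) -> np.ndarray:
    """Integrate the population over time from rest.

    ``v_cx_t`` has shape (T, H, W, N); returns the end-stopped activity at
    every step, same shape.  Gamma is computed from the complex-V1 field of
    the same step unless supplied.
    """
    T = v_cx_t.shape[0]
    if gamma_t is None:
        gamma_t = inhibition_field(v_cx_t, p)
    out = np.zeros_like(v_cx_t)
    v = np.zeros(v_cx_t.shape[1:])
    for t in range(T):
        v = endstopped_step(v, v_cx_t[t], p, gamma=gamma_t[t])
        out[t] = v
    return out
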