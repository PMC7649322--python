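"""Adaptive surround modulation of MT units.

The surround of an MT unit switches between facilitatory and antagonistic
as a function of two local image measurements taken over the same 7x7
(M = 49 unit) window as the MT surround itself:

* ``Lambda`` — local contrast: mean absolute intensity difference between
  the center pixel and its window neighbours.
* ``Delta`` — motion discontinuity: cosine-weighted sum of complex-V1
  activity in *other* direction channels across the window, normalized by
  10 M and clipped to [0, 1].

The modulation term is

    chi = k * S(|a| * (k (Lambda - c_r) - 1 + b Delta + alpha * beta)) - 1,

with ``S`` the logistic sigmoid, ``alpha = 1 - (Lambda - c_r)`` the
coherency-from-contrast term and ``beta = 1 - Delta`` the
coherency-from-motion term.  Positive ``chi`` is suppressive, negative is
facilitatory; it saturates at ``k - 1`` (= 1 at defaults) and crosses zero
at ``Lambda = c_r`` when ``Delta = 0``.  The slope constant ``a`` enters as
a magnitude so that suppression *increases* with contrast and with
discontinuity, and the slope multiplies the entire bracket — the only
arrangement that yields both sign crossovers the model is built around.
The whole term is gated by the center: ``chi = 0`` wherever the MT unit it
modulates is inactive.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import brentq

from .config import ModelParams

__all__ = ["local_contrast", "sustained_contrast", "causal_running_max",
           "motion_discontinuity",
           "surround_modulation", "chi", "crossover_contrast",
           "sweep_chi_vs_delta", "sweep_chi_vs_lambda"]


def local_contrast(frame: np.ndarray, p: ModelParams) -> np.ndarray:
    """Local contrast ``Lambda``: (1/M) sum of |I_center - I_neighbour|
    over the 7x7 window.

    ``frame`` is (H, W) or (T, H, W); out-of-frame neighbours contribute 0
    (as if they carried the center's intensity).  Result is in [0, 1] for
    intensities in [0, 1].
    """
    f = np.asarray(frame, dtype=np.float64)
    squeeze = f.ndim == 2
    if squeeze:
        f = f[None]
    hw = p.surround_halfwidth
    H, W = f.shape[1:]
    acc = np.zeros_like(f)
    for di in range(-hw, hw + 1):
        for dj in range(-hw, hw + 1):
            if di == 0 and dj == 0:
                continue
            src_r = slice(max(di, 0), H + min(di, 0))
            dst_r = slice(max(-di, 0), H + min(-di, 0))
            src_c = slice(max(dj, 0), W + min(dj, 0))
            dst_c = slice(max(-dj, 0), W + min(-dj, 0))
            acc[:, dst_r, dst_c] += np.abs(f[:, dst_r, dst_c] - f[:, src_r, src_c])
    lam = acc / p.M
    return lam[0] if squeeze else lam


def causal_running_max(arr: np.ndarray, k: int) -> np.ndarray:
    """``out[t] = max(arr[max(0, t-k+1) .. t])`` along axis 0."""
    out = np.empty_like(arr)
    for t in range(arr.shape[0]):
        out[t] = arr[max(0, t - k + 1):t + 1].max(axis=0)
    return out


def sustained_contrast(lam: np.ndarray, p: ModelParams,
                       span: float = 0.3) -> np.ndarray:
    """Contrast field aligned with the footprint of the motion signals it
    gates: a causal running maximum in time and a local maximum in space.

    The V1 motion signals that the surround modulates persist for the
    duration of the temporal filters (about ``span`` time units) and are
    smeared several pixels beyond a contour by the Gabor envelope.  Gating
    them with the *instantaneous, pixel-local* frame contrast would mark
    the wake behind a moving contour and the flanks beside it as
    low-contrast (facilitatory) zones and ignite spurious activity there;
    holding each location's contrast at its recent maximum over the
    surround half-width keeps the surround sign consistent with the motion
    signals it acts on.

    ``lam`` is (T, H, W); returns the same shape with
    ``out[t] = max over the +-halfwidth window of max(lam[t-K+1 .. t])``
    for ``K = round(span / dt)``.
    """
    from scipy.ndimage import maximum_filter
    k = max(1, round(span / p.dt))
    hw = p.surround_halfwidth
    T = lam.shape[0]
    dil = maximum_filter(lam, size=(1, 2 * hw + 1, 2 * hw + 1),
                         mode="constant")
    return causal_running_max(dil, k)


def motion_discontinuity(v_cx: np.ndarray, p: ModelParams) -> np.ndarray:
    """Motion discontinuity ``Delta``, shape like ``v_cx`` (..., H, W, N).

    For channel theta: window sum of sum_psi (1 - cos(psi - theta)) *
    v_cx(psi), divided by 10 M and clipped to [0, 1].  The psi = theta term
    carries weight zero, so including it is harmless; out-of-frame
    neighbours contribute zero.
    """
    v = np.asarray(v_cx, dtype=np.float64)
    th = np.deg2rad(np.asarray(p.directions))
    wmat = 1.0 - np.cos(th[None, :] - th[:, None])  # [theta, psi]
    weighted = v @ wmat.T                            # (..., H, W, N_theta)
    hw = p.surround_halfwidth
    size = 2 * hw + 1
    ax = (v.ndim - 3, v.ndim - 2)
    sizes = [1] * v.ndim
    for a in ax:
        sizes[a] = size
    # uniform_filter(mode="constant") averages with zero padding; the
    # window *sum* is that mean times the window area.
    box = uniform_filter(weighted, size=sizes, mode="constant") * size ** 2
    return np.clip(box / (10.0 * p.M), 0.0, 1.0)


def chi(lam, delta, p: ModelParams):
    """Modulation term for an *active* center (no gate), elementwise.

    Accepts scalars or broadcastable arrays; returns values in
    ``(-1, k - 1)``.
    """
    lam = np.asarray(lam, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    alpha = 1.0 - (lam - p.c_r)
    beta = 1.0 - delta
    inner = p.k * (lam - p.c_r) - 1.0 + p.b * delta + alpha * beta
    arg = abs(p.a) * inner
    s = 1.0 / (1.0 + np.exp(-arg))
    return p.k * s - 1.0


def surround_modulation(lam: np.ndarray, delta: np.ndarray,
                        v_mt: np.ndarray, p: ModelParams) -> np.ndarray:
    """Surround field ``chi`` gated by center activity.

    ``lam`` is (H, W) (broadcast over channels), ``delta`` and ``v_mt`` are
    (H, W, N).  Returns (H, W, N); zero wherever ``v_mt <= 0``.
    """
    lam = np.asarray(lam, dtype=np.float64)
    if lam.ndim == np.asarray(delta).ndim - 1:
        lam = lam[..., None]
    field = chi(lam, delta, p)
    return np.where(np.asarray(v_mt) > 0.0, field, 0.0)


def crossover_contrast(p: ModelParams, delta: float = 0.0,
                       tol: float = 1e-12) -> float:
    """Contrast at which ``chi`` changes sign, by root-finding on [0, 1].

    At ``delta = 0`` the bracket reduces to ``Lambda - c_r``, so the root is
    exactly ``c_r``; the function solves the full expression numerically
    rather than returning the closed form.
    """
    fn = lambda lam: chi(lam, delta, p)
    lo, hi = 0.0, 1.0
    if fn(lo) * fn(hi) > 0:
        raise ValueError("chi does not change sign on [0, 1] at this delta")
    return float(brentq(fn, lo, hi, xtol=tol, rtol=8.9e-16))


def sweep_chi_vs_delta(p: ModelParams, lam: float = 0.0,
                       n: int = 201) -> np.ndarray:
    """(n, 2) array of (Delta, chi) at fixed contrast ``lam``."""
    d = np.linspace(0.0, 1.0, n)
    return np.column_stack([d, chi(lam, d, p)])


def sweep_chi_vs_lambda(p: ModelParams, delta: float = 0.0,
                        n: int = 201) -> np.ndarray:
    """(n, 2) array of (Lambda, chi) at fixed discontinuity ``delta``."""
    lam = np.linspace(0.0, 1.0, n)
    return np.column_stack([lam, chi(lam, delta, p)])
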