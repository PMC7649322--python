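"""Recurrent MT population dynamics with delayed inhibition.

Each MT unit integrates four excitatory drives (complex V1, thresholded
end-stopped V1, ECRF-gated V1, and lateral excitation from like-tuned
neighbours), two delayed inhibitory fields (same-location cross-direction
inhibition and long-range cross-direction inhibition, both read from the
population state ``T_in`` in the past), a decay term, and the adaptive
surround term ``chi``:

    rhs = Gmtcx v_cx + Gmtes v_es' + Gmtmt_ex lambda + Gcsmt kappa
        - Gmtmt_inter gamma(t - T_in) - Gmtmt3 xi(t - T_in)
        - tau_mt v_mt - chi

The state update is a clipped forward-Euler step, ``v <- h(v + dt * rhs)``
with ``h`` the piecewise-linear saturation onto [0, 1] — i.e. ``h`` acts as
a state saturation, which preserves the intended range while still allowing
activity to decay.  (Applying ``h`` to the derivative itself, which forces
monotone growth, is available behind the ``literal_derivative_saturation``
config flag for comparison.)  Before the delay buffer has filled (the
first ``T_in/dt = 40`` steps at defaults) the delayed fields are zero.

Modes: in *component* mode the ECRF-gated drive enters with gain ``Gcsmt``
and lateral excitation is gated by ECRF form activity; in *pattern* mode
the ECRF projection is absent (``Gcsmt = 0``) and the lateral-excitation
gate is forced open, so motion signals originating at the visible junction
can propagate along the whole figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter

from .config import ModelParams
from .stimuli import FrameSequence
from .v1_motion_energy import complex_v1_response
from .v1_endstopped import (endstopped_equilibrium, endstopped_response,
                            inhibition_field)
from .v1_ecrf import ecrf_response, form_gate
from .mt_surround import (causal_running_max, chi, local_contrast,
                          motion_discontinuity, sustained_contrast)

__all__ = ["MTState", "SimulationTrace", "lateral_excitation",
           "interdirectional_inhibition", "longrange_inhibition",
           "mt_step", "run_model", "saturate"]


def saturate(x: np.ndarray) -> np.ndarray:
    """Piecewise-linear saturation ``h`` onto [0, 1]."""
    return np.clip(x, 0.0, 1.0)


def _box_sum(v: np.ndarray, halfwidth: int) -> np.ndarray:
    """Zero-padded square window sum over the two spatial axes of
    (..., H, W, N)."""
    size = 2 * halfwidth + 1
    sizes = [1] * v.ndim
    sizes[-3] = sizes[-2] = size
    return uniform_filter(v, size=sizes, mode="constant") * size ** 2


def lateral_excitation(v_mt: np.ndarray, v_cs: np.ndarray, p: ModelParams,
                       gate_open: bool = False) -> np.ndarray:
    """Lateral excitation ``lambda`` between like-tuned MT neighbours.

    The 7x7 window sum of same-channel activity, passed only where the sum
    minus the center's own activity exceeds ``T_mt`` *and* the ECRF form
    gate is open (summed ``v_cs`` strictly positive).  ``gate_open=True``
    bypasses the form gate (pattern mode).
    """
    s = _box_sum(v_mt, p.surround_halfwidth)
    cond = (s - v_mt) > p.T_mt
    if not gate_open:
        cond = cond & (np.asarray(v_cs).sum(axis=-1) > 0.0)[..., None]
    return np.where(cond, s, 0.0)


def interdirectional_inhibition(v_mt: np.ndarray) -> np.ndarray:
    """Same-location inhibition ``gamma``: sum of the other channels."""
    return v_mt.sum(axis=-1, keepdims=True) - v_mt


def longrange_inhibition(v_mt: np.ndarray, p: ModelParams) -> np.ndarray:
    """Long-range inhibition ``xi``: other-channel activity summed over the
    (2 phi + 1)^2 window (center location included)."""
    box = _box_sum(v_mt, p.phi)
    return box.sum(axis=-1, keepdims=True) - box


@dataclass
class MTState:
    """Population state plus the ring buffer of past states used for the
    delayed inhibition."""

    v_mt: np.ndarray                 # (H, W, N)
    buffer: np.ndarray               # (delay_steps, H, W, N), ring
    head: int = 0                    # next slot to overwrite
    steps: int = 0                   # total steps taken

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], p: ModelParams) -> "MTState":
        return cls(v_mt=np.zeros(shape),
                   buffer=np.zeros((p.delay_steps,) + shape))

    def delayed(self) -> np.ndarray:
        """State ``delay_steps`` in the past (zeros during warm-up)."""
        return self.buffer[self.head]

    def push(self, v: np.ndarray) -> None:
        self.buffer[self.head] = v
        self.head = (self.head + 1) % self.buffer.shape[0]
        self.steps += 1


def mt_step(state: MTState, drives: dict, p: ModelParams) -> MTState:
    """Advance the MT population by one Euler step.

    ``drives`` must contain ``v_cx``, ``v_es``, ``kappa``, ``chi`` (the
    *ungated* surround field), ``lam_ex`` (lateral excitation),
    ``gamma_delayed`` and ``xi_delayed``, all (H, W, N); ``Gcsmt`` may
    override the params gain (mode switch).

    The surround term applies only to active centers, which makes the
    right-hand side discontinuous at v = 0.  A naive Euler step chatters
    across that switching surface (the unit flickers on, is pushed back by
    the surround, flickers on again), producing a spurious standing
    background that the lateral excitation then amplifies.  The gate is
    therefore evaluated on the provisional state: a unit at rest whose
    base drive cannot overcome its surround stays exactly at rest, the
    sliding-mode solution of the stated dynamics.
    """
    v = state.v_mt
    v_es = drives["v_es"]
    if p.apply_rho_es:
        v_es = np.where(v_es > p.rho_es, v_es, 0.0)
    gcsmt = drives.get("Gcsmt", p.Gcsmt)
    base = (p.Gmtcx * drives["v_cx"] + p.Gmtes * v_es
            + p.Gmtmt_ex * drives["lam_ex"] + gcsmt * drives["kappa"]
            - p.Gmtmt_inter * drives["gamma_delayed"]
            - p.Gmtmt3 * drives["xi_delayed"]
            - p.tau_mt * v)
    active = (v > 0.0) | (v + p.dt * base > 0.0)
    rhs = base - np.where(active, drives["chi"], 0.0)
    if p.literal_derivative_saturation:
        new = v + p.dt * saturate(rhs)
    else:
        new = saturate(v + p.dt * rhs)
    state.push(v)
    state.v_mt = new
    return state


#: a channel counts as locally favoured if its end-stopped equilibrium is
#: within this factor of the local best channel's
PREFERENCE_BAND = 0.9


def form_motion_drive(v_cx: np.ndarray, v_cs: np.ndarray,
                      gamma: np.ndarray, p: ModelParams,
                      band: float = PREFERENCE_BAND) -> np.ndarray:
    """The form-gated V1 motion drive ``kappa`` as the MT stage receives it.

    The interaction of form and motion information passes complex-V1 motion
    only where ECRF form units are active (at terminator-level form
    responses, :func:`~mtsurround.v1_ecrf.form_gate`) and, there, only in
    the direction channels that the end-stopping circuit locally favours —
    the channels whose lateral-inhibition-discounted (end-stopped)
    equilibrium is within ``band`` of the local best.  At a visible
    terminator that is the true motion of the contour end; on an extended
    contour with no competing 2-D feature it is the edge-normal (aperture)
    channel, the only candidate there.  This keeps the strong ``Gcsmt``
    pathway from seeding the recurrent MT layer with ambiguous edge motion
    wherever an unambiguous signal coexists.
    """
    eq = endstopped_equilibrium(v_cx, gamma, p)
    favoured = eq >= band * eq.max(axis=-1, keepdims=True)
    gate = form_gate(v_cs)[..., None]
    return np.where(gate & favoured, v_cx, 0.0)


@dataclass
class SimulationTrace:
    """Full record of one run: per-step MT activity, the surround field,
    the V1 streams that drove it, and the final delay buffer."""

    v_mt: np.ndarray        # (T, H, W, N)
    chi: np.ndarray         # (T, H, W, N)
    v_cx: np.ndarray        # (T, H, W, N)
    v_es: np.ndarray        # (T, H, W, N)
    v_cs: np.ndarray        # (T, H, W, O)
    kappa: np.ndarray       # (T, H, W, N)
    lam: np.ndarray         # (T, H, W) local contrast
    delta: np.ndarray       # (T, H, W, N) motion discontinuity
    buffer: np.ndarray      # final delay-buffer contents, time-ordered
    mode: str = "component"
    params_yaml: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.v_mt.shape[0]


def run_model(frames: FrameSequence, p: ModelParams,
              mode: Literal["component", "pattern"] = "component",
              gcsmt: float | None = None) -> SimulationTrace:
    """Run the full V1 -> MT pipeline on a stimulus.

    One integration step per stimulus frame.  ``mode='component'`` uses the
    ECRF projection at gain ``p.Gcsmt``; ``mode='pattern'`` removes it and
    opens the lateral-excitation gate.  ``gcsmt`` overrides the projection
    gain in either mode (the pattern/component distinction is a continuous
    dial in the model; the two named modes are its endpoints).

    Raises ``FloatingPointError`` naming the step if any state goes
    non-finite.
    """
    from .config import serialize_params

    if mode not in ("component", "pattern"):
        raise ValueError(f"mode must be 'component' or 'pattern', got {mode!r}")
    arr = frames.frames
    T, H, W = arr.shape

    v_cx = complex_v1_response(arr, p)
    v_cs = ecrf_response(arr, p)
    # the form stream carries the same temporal persistence as the motion
    # stream it gates (see sustained_contrast)
    v_cs_sust = causal_running_max(v_cs, max(1, round(0.3 / p.dt)))
    gamma_t = inhibition_field(v_cx, p)
    kappa = form_motion_drive(v_cx, v_cs_sust, gamma_t, p)
    v_es = endstopped_response(v_cx, p, gamma_t=gamma_t)
    lam = sustained_contrast(local_contrast(arr, p), p)
    delta = motion_discontinuity(v_cx, p)

    if gcsmt is None:
        gcsmt = 0.0 if mode == "pattern" else p.Gcsmt
    gate_open = mode == "pattern"

    state = MTState.zeros((H, W, p.N), p)
    v_mt_t = np.zeros((T, H, W, p.N))
    chi_t = np.zeros((T, H, W, p.N))
    for t in range(T):
        v_del = state.delayed()
        field = chi(lam[t][..., None], delta[t], p)
        drives = {
            "v_cx": v_cx[t],
            "v_es": v_es[t],
            "kappa": kappa[t],
            "chi": field,
            "lam_ex": lateral_excitation(state.v_mt, v_cs_sust[t], p,
                                         gate_open=gate_open),
            "gamma_delayed": interdirectional_inhibition(v_del),
            "xi_delayed": longrange_inhibition(v_del, p),
            "Gcsmt": gcsmt,
        }
        state = mt_step(state, drives, p)
        # record the surround field as applied (zero at inactive centers)
        chi_t[t] = np.where(state.v_mt > 0.0, field, 0.0)
        if not np.isfinite(state.v_mt).all():
            raise FloatingPointError(f"non-finite MT activity at step {t}")
        v_mt_t[t] = state.v_mt

    # time-ordered buffer (oldest first) for lossless resume
    order = (np.arange(p.delay_steps) + state.head) % p.delay_steps
    trace = SimulationTrace(
        v_mt=v_mt_t, chi=chi_t, v_cx=v_cx, v_es=v_es, v_cs=v_cs,
        kappa=kappa, lam=lam, delta=delta, buffer=state.buffer[order],
        mode=mode, params_yaml=serialize_params(p),
        meta={"gcsmt": gcsmt, "n_steps": T, "shape": [H, W, p.N]})
    return trace
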