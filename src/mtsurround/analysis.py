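"""Metrics on simulation traces: direction decoding, disambiguation
latency, terminator selectivity, and pattern/component classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelParams
from .mt_dynamics import SimulationTrace
from .stimuli import GroundTruth

__all__ = ["DecodedMap", "DisambiguationReport", "decode_directions",
           "time_to_disambiguation", "terminator_edge_ratio",
           "pattern_component_class", "DEFAULT_DECODE_THRESHOLD",
           "DEFAULT_CRITERION"]

DEFAULT_DECODE_THRESHOLD = 0.05
DEFAULT_CRITERION = 0.9

#: label value meaning "no channel above threshold"
NONE_LABEL = -1


@dataclass
class DecodedMap:
    """Per-location dominant direction channel (or ``-1`` for none) and the
    dominance margin (best minus second-best channel activity)."""

    labels: np.ndarray   # (H, W) int
    margin: np.ndarray   # (H, W) float
    threshold: float


def decode_directions(snapshot: np.ndarray,
                      threshold: float = DEFAULT_DECODE_THRESHOLD) -> DecodedMap:
    """Decode an (H, W, N) activity snapshot to a direction label map.

    Argmax over channels where the maximum exceeds ``threshold``; exact
    ties break to the lowest channel index (np.argmax convention).
    """
    snap = np.asarray(snapshot, dtype=np.float64)
    labels = snap.argmax(axis=-1).astype(np.int64)
    best = snap.max(axis=-1)
    part = np.sort(snap, axis=-1)
    second = part[..., -2] if snap.shape[-1] > 1 else np.zeros_like(best)
    labels[best <= threshold] = NONE_LABEL
    return DecodedMap(labels=labels, margin=best - second, threshold=threshold)


@dataclass
class DisambiguationReport:
    """Time for the decoded map to reach the veridical bar directions.

    ``latency_steps`` is the first step at which the fraction of on-bar
    locations decoded correctly reaches ``criterion``, or ``None``
    ("never"); ``latency`` / ``latency_ms`` express it in time units / ms.
    """

    trajectory: np.ndarray       # (T,) fraction correct per step
    criterion: float
    threshold: float
    latency_steps: int | None
    latency: float | None        # time units
    latency_ms: float | None

    @property
    def never(self) -> bool:
        return self.latency_steps is None


def _per_step_fraction(v_mt_t: np.ndarray, gt: GroundTruth,
                       threshold: float) -> np.ndarray:
    T = v_mt_t.shape[0]
    frac = np.zeros(T)
    for t in range(T):
        dec = decode_directions(v_mt_t[t], threshold)
        correct = 0
        total = 0
        for b, ch in enumerate(gt.true_channels):
            mask = gt.on_bar[b][t]
            total += int(mask.sum())
            correct += int((dec.labels[mask] == ch).sum())
        if total == 0:
            raise ValueError(f"empty on-bar masks at frame {t}")
        frac[t] = correct / total
    return frac


def time_to_disambiguation(trace: SimulationTrace, gt: GroundTruth,
                           p: ModelParams,
                           criterion: float = DEFAULT_CRITERION,
                           threshold: float = DEFAULT_DECODE_THRESHOLD,
                           ) -> DisambiguationReport:
    """Latency until >= ``criterion`` of on-bar locations decode veridically.

    The fraction-correct trajectory counts, per step, on-bar locations whose
    decoded label equals their bar's true direction channel.  Latency is the
    first step at/above criterion, converted with the step size and the
    ms-per-time-unit reporting scale.  A location on both bars counts for
    each bar it belongs to.
    """
    frac = _per_step_fraction(trace.v_mt, gt, threshold)
    hits = np.nonzero(frac >= criterion)[0]
    if hits.size == 0:
        return DisambiguationReport(frac, criterion, threshold, None, None, None)
    step = int(hits[0])
    latency = step * p.dt
    return DisambiguationReport(frac, criterion, threshold, step, latency,
                                latency * p.ms_per_time_unit)


def terminator_edge_ratio(activity: np.ndarray, gt: GroundTruth,
                          t: int = -1) -> float:
    """Mean activity over terminators divided by mean over mid-edges.

    ``activity`` is (H, W) or (H, W, N) (channels are summed).  Terminator
    mask is the union of intrinsic and extrinsic terminators at frame
    ``t``.  Returns ``inf`` when the mid-edge mean is zero; raises if
    either mask is empty.
    """
    act = np.asarray(activity, dtype=np.float64)
    if act.ndim == 3:
        act = act.sum(axis=-1)
    term = gt.intrinsic[t] | gt.extrinsic[t]
    mid = gt.mid_edge[t]
    if not term.any() or not mid.any():
        raise ValueError("terminator or mid-edge mask is empty; "
                         "ratio undefined")
    num = float(act[term].mean())
    den = float(act[mid].mean())
    if den == 0.0:
        return float("inf")
    return num / den


#: channel carrying the plaid's coherent (pattern) motion: upward
PATTERN_CHANNEL = 2
#: channels carrying the two bars' component (edge-normal) motions
COMPONENT_CHANNELS = (1, 3)


def channel_mass(v_mt_t: np.ndarray, gt: GroundTruth,
                 window: int = 10) -> np.ndarray:
    """Mean per-channel activity over on-bar locations, averaged over the
    last ``window`` steps."""
    T = v_mt_t.shape[0]
    w = min(window, T)
    mass = np.zeros(v_mt_t.shape[-1])
    for t in range(T - w, T):
        union = np.zeros(v_mt_t.shape[1:3], dtype=bool)
        for m in gt.on_bar:
            union |= m[t]
        if union.any():
            mass += v_mt_t[t][union].mean(axis=0)
    return mass / w


def pattern_component_class(trace: SimulationTrace, gt: GroundTruth,
                            window: int = 10) -> str:
    """Classify a plaid run as ``"pattern"``, ``"component"`` or ``"mixed"``.

    "pattern" if the upward channel carries the largest steady-state
    on-bar mass; "component" if one of the two oblique (up-left/up-right)
    channels does; "mixed" otherwise.
    """
    mass = channel_mass(trace.v_mt, gt, window)
    top = int(mass.argmax())
    if mass.max() == 0.0:
        return "mixed"
    if top == PATTERN_CHANNEL:
        return "pattern"
    if top in COMPONENT_CHANNELS:
        return "component"
    return "mixed"
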