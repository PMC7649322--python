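"""Model constants and simulation conventions.

All gains, thresholds, filter parameters and grid conventions used anywhere
in the model live in a single :class:`ModelParams` object, so that every
symbol in the model equations resolves to exactly one field here.  Values
are serialized to/from YAML; the shipped ``data/defaults.yaml`` file holds
the canonical defaults.

Two naming notes that matter when reading the code against the usual
presentation of this model family:

* The MT lateral-excitation gain ``Gmtmt_ex`` (1.0) multiplies the lateral
  excitation field and ``Gmtmt_inter`` (0.1) multiplies the same-location
  cross-direction inhibition, following the MT rate equation as written
  (its first recurrent gain multiplies the excitation term).  The legacy
  labels ``Gmtmt1``/``Gmtmt2`` are accepted as config aliases for these
  two, in that order.  Strong lateral excitation is what lets unambiguous
  terminator signals claim whole contours; with the two gains swapped the
  propagating wave never forms.
* The surround-suppression slope ``a`` is stored as a magnitude (10).  The
  sigmoid argument uses ``+|a|`` so that surround suppression *increases*
  with local contrast and with motion discontinuity, which is the behaviour
  the modulation-curve analyses require (see :mod:`mtsurround.mt_surround`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParams", "ParamValidationError", "load_params", "validate_params",
           "serialize_params", "save_params", "DEFAULTS_FILE"]

DEFAULTS_FILE = Path(__file__).parent / "data" / "defaults.yaml"

#: config keys accepted as aliases (legacy gain labels, bound by function)
_ALIASES = {"Gmtmt1": "Gmtmt_ex", "Gmtmt2": "Gmtmt_inter"}


class ParamValidationError(ValueError):
    """A parameter document parsed but violated a model invariant."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class ModelParams:
    """Every constant of the model, plus grid/time conventions.

    Units: gains and thresholds are dimensionless activity units; spatial
    SDs and frequencies are in degrees of visual angle; times are in
    simulation time units (1 time unit = 1 s, so ``dt = 0.01`` is a 10 ms
    step under ``ms_per_time_unit = 1000``).
    """

    # --- V1 end-stopped stage ---
    Gescx1: float = 2.0    # drive gain, complex V1 -> end-stopped
    Gescx2: float = 3.0    # gain of lateral inhibition onto end-stopped units
    rho_cx: float = 0.13   # complex-V1 activity threshold for lateral inhibition
    rho_es: float = 0.3    # end-stopped activity threshold before MT projection
    tau_es: float = 0.01   # end-stopped decay rate

    # --- MT afferent gains ---
    Gmtcx: float = 0.5     # complex V1 -> MT
    Gmtes: float = 1.0     # end-stopped -> MT
    Gcsmt: float = 2.0     # ECRF-gated V1 drive -> MT (0 in pattern mode)

    # --- MT recurrent gains ---
    Gmtmt_ex: float = 1.0     # lateral excitation between like-tuned MT units
    Gmtmt_inter: float = 0.1  # same-location inter-directional inhibition
    Gmtmt3: float = 1.0       # long-range inter-directional inhibition
    phi: int = 6              # half-width of the long-range inhibition window
    T_mt: float = 0.001       # MT activity threshold (lateral-excitation gate)
    tau_mt: float = 0.01      # MT decay rate
    T_in: float = 0.4         # delay of the recurrent inhibition, time units

    # --- adaptive surround ---
    M: int = 49        # surround extent: number of units in the 7x7 window
    c_r: float = 0.2   # contrast threshold where surround flips sign
    a: float = 10.0    # suppression slope vs contrast (stored as magnitude)
    b: float = 2.4     # suppression slope vs motion discontinuity
    k: float = 2.0     # saturation constant: chi saturates at k - 1

    # --- population layout ---
    N: int = 8   # direction channels (45 deg apart)
    O: int = 4   # ECRF orientation channels (0, 45, 90, 135 deg)

    # --- motion-energy front end ---
    f: float = 1.1        # spatial frequency, cycles/deg
    sigma_x: float = 0.5  # Gabor SD along the carrier, deg
    sigma_y: float = 0.5  # Gabor SD across the carrier, deg
    n_fast: int = 6       # order of the fast temporal filter
    n_slow: int = 9       # order of the slow temporal filter
    tau_g: float = 0.01   # temporal-filter time constant

    # --- ECRF difference-of-Gaussians ---
    sigma_xc: float = 0.35  # center SD along orientation, deg
    sigma_yc: float = 0.4   # center SD across orientation, deg
    sigma_xs: float = 0.4   # surround SD along orientation, deg
    sigma_ys: float = 0.5   # surround SD across orientation, deg
    A_c: float = 1.0        # center gain
    A_s: float = 0.72       # surround gain

    # --- integration & grid conventions ---
    dt: float = 0.01            # simulation step, time units
    deg_per_pixel: float = 0.25  # one model unit per stimulus pixel
    ms_per_time_unit: float = 1000.0  # reporting scale

    # --- behaviour switches ---
    apply_rho_es: bool = True  # threshold end-stopped output before MT
    literal_derivative_saturation: bool = False  # saturate rhs, not state

    # -- derived helpers -------------------------------------------------

    @property
    def delay_steps(self) -> int:
        """Length of the delayed-inhibition buffer, in integration steps."""
        return round(self.T_in / self.dt)

    @property
    def surround_halfwidth(self) -> int:
        """Half-width of the square surround window (M=49 -> 7x7 -> 3)."""
        return (round(math.isqrt(self.M)) - 1) // 2

    @property
    def directions(self):
        """Preferred directions in degrees, channel i -> 45*i."""
        return tuple(360.0 * i / self.N for i in range(self.N))

    @property
    def orientations(self):
        """ECRF preferred orientations in degrees."""
        return tuple(180.0 * i / self.O for i in range(self.O))

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def validate_params(p: ModelParams) -> list[str]:
    """Return a list of invariant violations (empty iff ``p`` is valid)."""
    v: list[str] = []

    def pos(name: str) -> None:
        if not getattr(p, name) > 0:
            v.append(f"{name}={getattr(p, name)!r}: must be strictly positive")

    for name in ("Gescx1", "Gescx2", "Gmtcx", "Gmtes", "Gmtmt_ex",
                 "Gmtmt_inter", "Gmtmt3", "sigma_x", "sigma_y", "sigma_xc",
                 "sigma_yc", "sigma_xs", "sigma_ys", "A_c", "A_s", "f",
                 "tau_g", "tau_es", "tau_mt", "dt", "deg_per_pixel",
                 "ms_per_time_unit", "rho_cx", "b", "a", "T_mt", "T_in"):
        pos(name)
    if p.Gcsmt < 0:
        v.append(f"Gcsmt={p.Gcsmt!r}: must be non-negative")
    if p.rho_es < 0:
        v.append(f"rho_es={p.rho_es!r}: must be non-negative")
    if p.N != 8:
        v.append(f"N={p.N!r}: the model is defined for 8 direction channels")
    if p.M != 49:
        v.append(f"M={p.M!r}: the surround window is fixed at 49 units (7x7)")
    if not 0 < p.c_r < 1:
        v.append(f"c_r={p.c_r!r}: must lie in (0, 1)")
    if not p.k >= 1:
        v.append(f"k={p.k!r}: must be >= 1")
    if not (isinstance(p.phi, int) and p.phi > 0):
        v.append(f"phi={p.phi!r}: must be a positive integer")
    if not (isinstance(p.O, int) and p.O >= 1):
        v.append(f"O={p.O!r}: must be a positive integer")
    for name in ("n_fast", "n_slow"):
        if not (isinstance(getattr(p, name), int) and getattr(p, name) >= 1):
            v.append(f"{name}={getattr(p, name)!r}: must be a positive integer")
    if p.dt > 0 and p.T_in > 0:
        ratio = p.T_in / p.dt
        if abs(ratio - round(ratio)) > 1e-9:
            v.append(f"T_in={p.T_in!r}: must be an integer multiple of dt={p.dt!r}")
    return v


def _coerce(name: str, value: Any) -> Any:
    ftypes = {f.name: f.type for f in fields(ModelParams)}
    t = ftypes[name]
    if t in ("int",) or t is int:
        if isinstance(value, bool) or (isinstance(value, float) and not value.is_integer()):
            raise ParamValidationError([f"{name}={value!r}: expected an integer"])
        return int(value)
    if t in ("float",) or t is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParamValidationError([f"{name}={value!r}: expected a number"])
        return float(value)
    if t in ("bool",) or t is bool:
        if not isinstance(value, bool):
            raise ParamValidationError([f"{name}={value!r}: expected a boolean"])
        return value
    return value


def load_params(source: str | Path | Mapping[str, Any] | None = None) -> ModelParams:
    """Build a :class:`ModelParams` from a YAML document or mapping.

    Absent keys take the model defaults; unknown keys are rejected.  The
    legacy gain labels ``Gmtmt1``/``Gmtmt2`` are accepted as aliases for
    ``Gmtmt_inter``/``Gmtmt_ex``.

    Parameters
    ----------
    source:
        ``None`` (pure defaults), a mapping, a YAML string, or a path to a
        YAML file.

    Raises
    ------
    yaml.YAMLError
        If the document does not parse (the error names the line).
    ParamValidationError
        If a key is unknown or an invariant is violated.
    """
    if source is None:
        doc: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text() if (
            isinstance(source, Path)
            or ("\n" not in str(source) and Path(str(source)).is_file())
        ) else str(source)
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ParamValidationError(
                [f"top-level document must be a mapping, got {type(loaded).__name__}"])
        doc = loaded

    known = {f.name for f in fields(ModelParams)}
    kwargs: dict[str, Any] = {}
    for key, value in doc.items():
        name = _ALIASES.get(key, key)
        if name not in known:
            raise ParamValidationError([f"unknown parameter {key!r}"])
        if name in kwargs:
            raise ParamValidationError([f"parameter {name!r} given more than once"])
        kwargs[name] = _coerce(name, value)

    p = ModelParams(**kwargs)
    violations = validate_params(p)
    if violations:
        raise ParamValidationError(violations)
    return p


def serialize_params(p: ModelParams) -> str:
    """Serialize to YAML with a stable field order (round-trips bytewise)."""
    data = {f.name: getattr(p, f.name) for f in fields(ModelParams)}
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=False)


def save_params(p: ModelParams, path: str | Path) -> None:
    Path(path).write_text(serialize_params(p))
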