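"""HDF5 persistence for simulation traces and run manifests.

One HDF5 file per run with named dimension labels: ``/mt/activity`` and
``/mt/surround`` are (t, y, x, direction); the V1 streams live under
``/v1/*``; the contrast and discontinuity fields under ``/surround/*``;
and the delay buffer under ``/state/buffer`` so a run can be resumed.
Round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py

from .config import ModelParams, load_params, serialize_params
from .mt_dynamics import SimulationTrace

__all__ = ["TraceFormatError", "RunManifest", "save_trace", "load_trace",
           "params_hash", "save_manifest", "load_manifest"]

FORMAT_VERSION = 1

_DATASETS = {
    "v_mt": ("mt/activity", ("t", "y", "x", "direction")),
    "chi": ("mt/surround", ("t", "y", "x", "direction")),
    "v_cx": ("v1/complex", ("t", "y", "x", "direction")),
    "v_es": ("v1/endstopped", ("t", "y", "x", "direction")),
    "v_cs": ("v1/ecrf", ("t", "y", "x", "orientation")),
    "kappa": ("v1/gated", ("t", "y", "x", "direction")),
    "lam": ("surround/contrast", ("t", "y", "x")),
    "delta": ("surround/discontinuity", ("t", "y", "x", "direction")),
    "buffer": ("state/buffer", ("t", "y", "x", "direction")),
}


class TraceFormatError(RuntimeError):
    """The file is not a readable trace of a supported version."""


def params_hash(p: ModelParams) -> str:
    """Content hash of a parameter set (stable across sessions)."""
    return hashlib.sha256(serialize_params(p).encode()).hexdigest()[:16]


def save_trace(trace: SimulationTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["mode"] = trace.mode
        f.attrs["params_yaml"] = trace.params_yaml
        f.attrs["meta_json"] = json.dumps(trace.meta)
        for attr, (name, dims) in _DATASETS.items():
            ds = f.create_dataset(name, data=getattr(trace, attr),
                                  compression="gzip", compression_opts=4)
            ds.attrs["dims"] = ",".join(dims)


def load_trace(path: str | Path) -> SimulationTrace:
    """Load a trace; raises :class:`TraceFormatError` on damaged or
    unsupported files (never crashes on truncation)."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise TraceFormatError(
                    f"unsupported trace format version {version} "
                    f"(expected {FORMAT_VERSION})")
            kwargs = {}
            for attr, (name, _) in _DATASETS.items():
                if name not in f:
                    raise TraceFormatError(f"missing dataset {name!r}")
                kwargs[attr] = f[name][()]
            return SimulationTrace(
                mode=str(f.attrs["mode"]),
                params_yaml=str(f.attrs["params_yaml"]),
                meta=json.loads(str(f.attrs["meta_json"])),
                **kwargs)
    except (OSError, KeyError) as exc:
        raise TraceFormatError(f"cannot read trace file {path}: {exc}") from exc


@dataclass
class RunManifest:
    """Everything needed to reproduce and post-process a run."""

    stimulus: dict
    params_hash: str
    params_yaml: str
    mode: str
    outputs: list[str] = field(default_factory=list)
    wall_clock_s: float | None = None

    def validate(self, base: Path) -> None:
        missing = [o for o in self.outputs if not (base / o).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        if params_hash(load_params(self.params_yaml)) != self.params_hash:
            raise ValueError("manifest params hash does not match its config")


def save_manifest(m: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(m.__dict__, indent=2, sort_keys=True))


def load_manifest(path: str | Path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))
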