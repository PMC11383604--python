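"""Data containers and file I/O for traces, profiles and parameter sets.

External units follow the acquisition conventions (micrometers,
nanonewtons, seconds); everything in memory is SI (m, N, s, Pa^-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .burgers import BurgersParams
from .geometry import Calibration, WireGeometry, ZProfileSet

__all__ = [
    "DisplacementTrace",
    "read_trace_csv",
    "write_trace_csv",
    "read_zprofiles_csv",
    "write_zprofiles_csv",
    "read_json",
    "write_json",
]

PathLike = Union[str, Path]

#: CSV column <-> channel name mapping for z-profile files.
_ZPROFILE_COLUMNS = {"ch_647": "membrane", "ch_bf": "brightfield", "ch_488": "particles"}


@dataclass(frozen=True)
class DisplacementTrace:
    """Sampled wire displacement under a recorded force waveform.

    t in seconds, x (displacement) in meters, force in newtons.
    """

    t: np.ndarray
    x: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.shape == x.shape == f.shape) or t.ndim != 1:
            raise ValueError("t, x and force must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return self.t.size

    @property
    def F0(self) -> float:
        """Applied force magnitude: median of the nonzero force samples, N."""
        on = self.force > 0.5 * self.force.max()
        if not np.any(on):
            raise ValueError("trace has no force-on samples")
        return float(np.median(self.force[on]))


def write_trace_csv(trace: DisplacementTrace, path: PathLike) -> None:
    on = trace.force > 0.5 * trace.force.max() if trace.force.max() > 0 else np.zeros(len(trace), bool)
    df = pd.DataFrame(
        {
            "time_s": trace.t,
            "displacement_um": trace.x * 1e6,
            "force_nN": trace.force * 1e9,
            "phase": np.where(on, "on", "off"),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path: PathLike) -> DisplacementTrace:
    df = pd.read_csv(path)
    required = {"time_s", "displacement_um", "force_nN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} is missing columns {sorted(missing)}")
    return DisplacementTrace(
        t=df["time_s"].to_numpy(float),
        x=df["displacement_um"].to_numpy(float) * 1e-6,
        force=df["force_nN"].to_numpy(float) * 1e-9,
    )


def write_zprofiles_csv(profiles: ZProfileSet, path: PathLike) -> None:
    data = {"z_um": profiles.z}
    for col, name in _ZPROFILE_COLUMNS.items():
        data[col] = profiles.channels[name]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_zprofiles_csv(path: PathLike) -> ZProfileSet:
    df = pd.read_csv(path)
    channels = {
        name: df[col].to_numpy(float) for col, name in _ZPROFILE_COLUMNS.items() if col in df
    }
    return ZProfileSet(z=df["z_um"].to_numpy(float), channels=channels)


def write_json(obj, path: PathLike) -> None:
    """Serialize a package object (or plain dict) to JSON."""
    if isinstance(obj, (BurgersParams, WireGeometry, Calibration)):
        obj = obj.to_dict()
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
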