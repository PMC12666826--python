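"""Reading and writing of load/displacement trace files.

Canonical CSV dialect: one header row, columns ``time_s``,
``displacement_mm``, ``load_n`` and optionally ``phase`` (integer protocol
phase), full float precision.  Vendor exports with different column names,
units or sign conventions are ingested through a :class:`ColumnMap`.

Ingest validates, it never repairs: non-uniform sampling, NaNs and short
files raise with row numbers instead of being silently resampled or
interpolated, because downstream event detection depends on the true
sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "ColumnMap",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "DEFAULT_COLUMN_MAP",
]

#: uniform-sampling tolerance: |dt - 1/fs| <= 1% of 1/fs
_DT_RTOL = 0.01
#: minimum trace length in seconds accepted at ingest
_MIN_DURATION_S = 1.0


class TraceFormatError(ValueError):
    """Raised for malformed trace files (missing columns, NaNs, bad sampling)."""


@dataclass
class Trace:
    """Uniformly sampled (time, displacement, load) record of one procedure.

    Units are seconds, millimetres and newtons; load and downward
    displacement are compression-positive.  ``command_phase`` is an optional
    integer channel giving the protocol phase commanded at each sample.
    """

    time: np.ndarray
    displacement: np.ndarray
    load: np.ndarray
    sample_rate: float
    command_phase: Optional[np.ndarray] = None
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.command_phase is not None:
            self.command_phase = np.asarray(self.command_phase)
        n = self.time.size
        if n < 2:
            raise TraceFormatError("trace must contain at least 2 samples")
        for name, ch in (
            ("displacement", self.displacement),
            ("load", self.load),
        ):
            if ch.size != n:
                raise TraceFormatError(
                    f"channel length mismatch: {name} has {ch.size} samples, "
                    f"time has {n}"
                )
        if self.command_phase is not None and self.command_phase.size != n:
            raise TraceFormatError("command_phase length mismatch")
        for name, ch in (
            ("time", self.time),
            ("displacement", self.displacement),
            ("load", self.load),
        ):
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise TraceFormatError(
                    f"non-finite value in column '{name}' at data row {bad[0] + 1}"
                )
        if self.sample_rate <= 0:
            raise TraceFormatError("sample_rate must be positive")
        dt_nominal = 1.0 / self.sample_rate
        dts = np.diff(self.time)
        bad = np.flatnonzero(np.abs(dts - dt_nominal) > _DT_RTOL * dt_nominal)
        if bad.size:
            i = int(bad[0])
            raise TraceFormatError(
                "non-uniform sampling: step between data rows "
                f"{i + 1} and {i + 2} is {dts[i]:.6g} s, expected "
                f"{dt_nominal:.6g} s (±1%)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from file columns to (s, mm, N) channels.

    ``*_scale`` are unit multipliers applied after reading (e.g. 1000 for a
    load column in kN); negative multipliers flip sign conventions.
    """

    time: str = "time_s"
    displacement: str = "displacement_mm"
    load: str = "load_n"
    phase: Optional[str] = "phase"
    time_scale: float = 1.0
    displacement_scale: float = 1.0
    load_scale: float = 1.0

    def __post_init__(self) -> None:
        if 0.0 in (self.time_scale, self.displacement_scale, self.load_scale):
            raise ValueError("unit multipliers must be non-zero")


DEFAULT_COLUMN_MAP = ColumnMap()


def read_trace(
    path: Union[str, Path], column_map: ColumnMap = DEFAULT_COLUMN_MAP
) -> Trace:
    """Read and validate a trace CSV.

    Raises :class:`TraceFormatError` naming the offending column/row for
    missing channels, NaNs, non-uniform sampling, or traces shorter than
    one second.
    """
    path = Path(path)
    # round_trip parser: exact float recovery of our own 17-digit output
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [
        c
        for c in (column_map.time, column_map.displacement, column_map.load)
        if c not in df.columns
    ]
    if missing:
        raise TraceFormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    time = df[column_map.time].to_numpy(dtype=float) * column_map.time_scale
    disp = (
        df[column_map.displacement].to_numpy(dtype=float)
        * column_map.displacement_scale
    )
    load = df[column_map.load].to_numpy(dtype=float) * column_map.load_scale
    phase = None
    if column_map.phase is not None and column_map.phase in df.columns:
        phase = df[column_map.phase].to_numpy()

    if time.size < 2:
        raise TraceFormatError(f"{path.name}: fewer than 2 data rows")
    dts = np.diff(time)
    med_dt = float(np.median(dts))
    if med_dt <= 0:
        raise TraceFormatError(f"{path.name}: time column is not increasing")
    if time[-1] - time[0] < _MIN_DURATION_S:
        raise TraceFormatError(
            f"{path.name}: trace spans {time[-1] - time[0]:.3g} s, "
            f"shorter than the {_MIN_DURATION_S:g} s minimum"
        )
    try:
        return Trace(
            time=time,
            displacement=disp,
            load=load,
            sample_rate=1.0 / med_dt,
            command_phase=phase,
            provenance={"path": str(path), "column_map": column_map},
        )
    except TraceFormatError as err:
        raise TraceFormatError(f"{path.name}: {err}") from None


def write_trace(trace: Trace, path: Union[str, Path]) -> Path:
    """Write a trace in the canonical dialect at full float precision.

    ``read_trace(write_trace(t))`` reproduces every channel bit-for-bit
    (floats are serialized with 17 significant digits).
    """
    if not isinstance(trace, Trace):
        raise TypeError("write_trace expects a Trace")
    path = Path(path)
    cols = {
        "time_s": trace.time,
        "displacement_mm": trace.displacement,
        "load_n": trace.load,
    }
    if trace.command_phase is not None:
        cols["phase"] = trace.command_phase
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return path
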