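"""Spatiotemporal map containers and their plain-text serialisation.

A spatiotemporal map is a sensors x time matrix of one scalar quantity
(diameter in mm or pressure in mmHg); rows are sensor locations along the gut
and columns are time samples on a uniform grid.  State maps hold the decoded
mechanical state per cell as integer codes in canonical state order.

File format (TSV): an optional ``# units: <unit>`` comment line, a header row
``position_mm <t_0> <t_1> ...`` with time coordinates in seconds, then one row
per sensor starting with its position in mm.  Readers accept tab or comma
dialects; writers emit tabs with shortest-exact float rendering so that a
write/read round trip reproduces values bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import N_STATES, STATES, MechanicalState

__all__ = [
    "SpatioTemporalMap",
    "StateMap",
    "read_map",
    "write_map",
    "read_state_map",
    "write_state_map",
    "SIMPLIFIED_NAMES",
]

_FMT = "%.17g"  # shortest representation that round-trips float64 exactly

# Integer coding of simplified maps.
SIMPLIFIED_NAMES = {0: "pas", 1: "ac", 2: "ar"}


@dataclass
class SpatioTemporalMap:
    """A sensors x time matrix of one measured quantity on a uniform grid."""

    values: np.ndarray                 # (n_sensors, n_samples)
    sensor_positions: np.ndarray       # mm, strictly increasing
    t0: float = 0.0                    # s
    dt: float = 0.25                   # s
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sensors x time matrix")
        if self.sensor_positions.shape != (self.values.shape[0],):
            raise ValueError("sensor_positions length must match the number of rows")
        if self.sensor_positions.size > 1 and not np.all(np.diff(self.sensor_positions) > 0):
            raise ValueError("sensor positions must be strictly increasing")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    def same_grid(self, other: "SpatioTemporalMap", rtol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.sensor_positions, other.sensor_positions, rtol=rtol)
            and np.isclose(self.t0, other.t0, rtol=rtol, atol=1e-12)
            and np.isclose(self.dt, other.dt, rtol=rtol)
        )


@dataclass
class StateMap:
    """Decoded mechanical states per sensor and sample, integer coded 0-11."""

    codes: np.ndarray                  # (n_sensors, n_samples) int
    sensor_positions: np.ndarray
    t0: float = 0.0
    dt: float = 0.25
    log_scores: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.intp)
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D sensors x time matrix")
        if self.sensor_positions.shape != (self.codes.shape[0],):
            raise ValueError("sensor_positions length must match the number of rows")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= N_STATES):
            raise ValueError("state codes must lie in [0, 11]")

    @property
    def n_sensors(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def states(self) -> list[list[MechanicalState]]:
        return [[STATES[c] for c in row] for row in self.codes]


def _write_matrix(path, matrix, positions, times, units, fmt) -> None:
    out = io.StringIO()
    if units:
        out.write(f"# units: {units}\n")
    out.write("position_mm\t" + "\t".join(_FMT % t for t in times) + "\n")
    for pos, row in zip(positions, matrix):
        out.write(_FMT % pos)
        for v in row:
            out.write("\t" + fmt % v)
        out.write("\n")
    Path(path).write_text(out.getvalue())


def _read_matrix(path):
    units = ""
    lines = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                stripped = line.lstrip().lstrip("#").strip()
                if stripped.lower().startswith("units:"):
                    units = stripped.split(":", 1)[1].strip()
                continue
            lines.append(line)
    if not lines:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, header=0, index_col=0,
                     float_precision="round_trip")
    times = df.columns.to_numpy(dtype=float)
    positions = df.index.to_numpy(dtype=float)
    return df.to_numpy(), positions, times, units


def _grid_from_times(times: np.ndarray) -> tuple[float, float]:
    if times.size < 2:
        return float(times[0]) if times.size else 0.0, 0.25
    dts = np.diff(times)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("time coordinates are not on a uniform grid")
    return float(times[0]), dt


def write_map(m: SpatioTemporalMap, path) -> None:
    """Serialise a scalar map to TSV."""
    _write_matrix(path, m.values, m.sensor_positions, m.times, m.units, _FMT)


def read_map(path) -> SpatioTemporalMap:
    """Read a scalar map from a TSV/CSV file written by :func:`write_map`."""
    values, positions, times, units = _read_matrix(path)
    t0, dt = _grid_from_times(times)
    return SpatioTemporalMap(values, positions, t0=t0, dt=dt, units=units)


def write_state_map(sm: StateMap, path, simplified: bool = False,
                    legend: bool = True) -> None:
    """Serialise a state map (codes 0-11, or 0-2 if *simplified*) plus legend.

    The legend sidecar ``<path>.legend.tsv`` maps each integer code to its
    state name and display colour.
    """
    path = Path(path)
    _write_matrix(path, sm.codes, sm.sensor_positions,
                  sm.t0 + sm.dt * np.arange(sm.n_samples), "state code", "%d")
    if not legend:
        return
    from .plotting import FULL_PALETTE, SIMPLIFIED_PALETTE

    with open(str(path) + ".legend.tsv", "w") as fh:
        fh.write("code\tname\tcolor\n")
        if simplified:
            for code, name in SIMPLIFIED_NAMES.items():
                fh.write(f"{code}\t{name}\t{SIMPLIFIED_PALETTE[code]}\n")
        else:
            for s in STATES:
                fh.write(f"{s.value}\t{s.label}\t{FULL_PALETTE[s.value]}\n")


def read_state_map(path) -> StateMap:
    """Read an integer-coded state map written by :func:`write_state_map`."""
    values, positions, times, _units = _read_matrix(path)
    t0, dt = _grid_from_times(times)
    return StateMap(values.astype(np.intp), positions, t0=t0, dt=dt)
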