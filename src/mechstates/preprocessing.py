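"""Baseline removal and alignment/binning onto a common spatiotemporal grid.

Diameter (video-derived) and pressure (catheter) maps are recorded at
different rates and with unknown relative offsets.  Before decoding they are
brought onto one shared grid: the coarsest time and space resolution of the
two inputs, shifted by user-supplied offsets, with each cell taking the mean
of the source samples that fall inside it.  Pressure baseline drift is
removed beforehand with an iterated Gaussian-minima lower envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .maps import SpatioTemporalMap

__all__ = ["AlignmentSpec", "remove_baseline", "remove_baseline_map", "align_and_bin"]


@dataclass
class AlignmentSpec:
    """How to place two maps on a common grid.

    ``temporal_offset`` and ``spatial_offset`` are added to the pressure
    map's coordinates to express them in the diameter map's frame (the
    offsets themselves come from an external synchronisation procedure and
    are supplied by the user).  Target resolutions default to the coarsest of
    the two inputs.
    """

    temporal_offset: float = 0.0   # s
    spatial_offset: float = 0.0    # mm
    target_dt: float | None = None
    target_dx: float | None = None


def _smooth_trend_safe(b: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with linear-extrapolation padding.

    Plain edge padding (constant or reflected) underestimates a trending
    signal near its ends, which makes the iterated-minimum envelope erode
    without bound there; extending both ends along their locally fitted
    slope keeps smoothing exact for linear trends.
    """
    n = b.size
    pad = min(int(np.ceil(4.0 * sigma)), n - 1)
    w = max(min(int(round(sigma)), n // 2), 2)
    i = np.arange(w)
    slope_l = np.polyfit(i, b[:w], 1)[0]
    slope_r = np.polyfit(i, b[-w:], 1)[0]
    ext = np.concatenate([
        b[0] - slope_l * np.arange(pad, 0, -1),
        b,
        b[-1] + slope_r * np.arange(1, pad + 1),
    ])
    return gaussian_filter1d(ext, sigma, mode="nearest")[pad:pad + n]


def remove_baseline(p, kernel_width: float = 10.0, iterations: int = 100,
                    dt: float = 0.1) -> np.ndarray:
    """Remove slow baseline drift from a pressure trace.

    The baseline is a lower envelope obtained by iterating
    ``b <- min(b, gaussian_smooth(b, kernel_width))`` starting from ``b = p``:
    smoothing pulls the curve below phasic peaks, the pointwise minimum keeps
    it under the signal, and iteration converges to a smooth curve tracking
    slow drift through the troughs.  The detrended trace ``p - b`` is
    returned; it is zero wherever the signal sits on its own lower envelope
    and re-applying the operation changes the result only negligibly.

    Parameters
    ----------
    kernel_width : float
        Gaussian smoothing width in seconds (default 10 s — longer than a
        phasic pressure peak, shorter than drift).
    iterations : int
        Number of smooth/minimum iterations (default 100).
    dt : float
        Sampling interval of the trace in seconds (pressure source rate is
        typically 10 Hz, so 0.1 s).
    """
    if not kernel_width > 0:
        raise ValueError("kernel_width must be positive")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not dt > 0:
        raise ValueError("dt must be positive")
    p = np.asarray(p, dtype=float)
    if p.size < 3:
        return np.zeros_like(p)
    sigma = kernel_width / dt
    b = p.copy()
    for _ in range(int(iterations)):
        b = np.minimum(b, _smooth_trend_safe(b, sigma))
    return p - b


def remove_baseline_map(m: SpatioTemporalMap, kernel_width: float = 10.0,
                        iterations: int = 100) -> SpatioTemporalMap:
    """Apply :func:`remove_baseline` to each sensor row of a pressure map."""
    values = np.stack(
        [remove_baseline(row, kernel_width, iterations, dt=m.dt) for row in m.values]
    )
    return SpatioTemporalMap(values, m.sensor_positions.copy(), t0=m.t0, dt=m.dt,
                             units=m.units)


def _spacing(positions: np.ndarray) -> float:
    if positions.size < 2:
        return 1.0
    return float(np.median(np.diff(positions)))


def _bin_onto(values, times, positions, t_start, dt, n_t, x_start, dx, n_x):
    """Mean-bin one source map onto the target grid; NaN where a cell is empty."""
    ti = np.floor((times - t_start) / dt + 1e-9).astype(int)
    xi = np.floor((positions - x_start) / dx + 1e-9).astype(int)
    tok = (ti >= 0) & (ti < n_t)
    xok = (xi >= 0) & (xi < n_x)
    sums = np.zeros((n_x, n_t))
    counts = np.zeros((n_x, n_t))
    for r in np.flatnonzero(xok):
        np.add.at(sums[xi[r]], ti[tok], values[r, tok])
        np.add.at(counts[xi[r]], ti[tok], 1.0)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def _fill_nearest(out: np.ndarray) -> np.ndarray:
    """Fill empty cells by the nearest filled cell in time (earlier wins ties);
    rows with no samples at all are filled from the nearest filled row."""
    n_x, n_t = out.shape
    cols = np.arange(n_t)
    for r in range(n_x):
        good = np.isfinite(out[r])
        if good.any() and not good.all():
            idx = np.flatnonzero(good)
            # nearest filled column; on ties np.searchsorted picks the earlier one
            pos = np.searchsorted(idx, cols)
            left = idx[np.clip(pos - 1, 0, idx.size - 1)]
            right = idx[np.clip(pos, 0, idx.size - 1)]
            nearest = np.where(cols - left <= right - cols, left, right)
            out[r] = out[r, nearest]
    rows_good = np.isfinite(out).all(axis=1)
    if not rows_good.all():
        if not rows_good.any():
            raise ValueError("binned map is entirely empty")
        good_rows = np.flatnonzero(rows_good)
        for r in np.flatnonzero(~rows_good):
            out[r] = out[good_rows[np.argmin(np.abs(good_rows - r))]]
    return out


def align_and_bin(diam: SpatioTemporalMap, pres: SpatioTemporalMap,
                  spec: AlignmentSpec | None = None
                  ) -> tuple[SpatioTemporalMap, SpatioTemporalMap]:
    """Bin a diameter and a pressure map onto one shared grid.

    The target grid uses the coarsest time and space resolution of the two
    inputs (unless overridden in *spec*), starts at the intersection of their
    extents, and labels each half-open cell ``[t, t+dt) x [x, x+dx)`` by its
    lower edge.  Cell values are arithmetic means of the source samples
    falling inside (intensive quantities); empty cells are filled by the
    nearest filled cell in time.  Both outputs share the identical coordinate
    arrays, so observation vectors can be assembled with no interpolation.
    """
    spec = spec or AlignmentSpec()
    if diam.values.size == 0 or pres.values.size == 0:
        raise ValueError("input maps must be non-empty")

    p_times = pres.times + spec.temporal_offset
    p_pos = pres.sensor_positions + spec.spatial_offset
    d_times = diam.times
    d_pos = diam.sensor_positions

    dx_d, dx_p = _spacing(d_pos), _spacing(p_pos)
    dt_t = spec.target_dt if spec.target_dt is not None else max(diam.dt, pres.dt)
    dx_t = spec.target_dx if spec.target_dx is not None else max(dx_d, dx_p)

    t_start = max(d_times[0], p_times[0])
    t_stop = min(d_times[-1] + diam.dt, p_times[-1] + pres.dt)
    x_start = max(d_pos[0], p_pos[0])
    x_stop = min(d_pos[-1] + dx_d, p_pos[-1] + dx_p)
    n_t = int(np.floor((t_stop - t_start) / dt_t + 1e-9))
    n_x = int(np.floor((x_stop - x_start) / dx_t + 1e-9))
    if n_t < 1 or n_x < 1:
        raise ValueError("diameter and pressure maps have no spatiotemporal overlap")

    d_out = _fill_nearest(_bin_onto(diam.values, d_times, d_pos, t_start, dt_t, n_t,
                                    x_start, dx_t, n_x))
    p_out = _fill_nearest(_bin_onto(pres.values, p_times, p_pos, t_start, dt_t, n_t,
                                    x_start, dx_t, n_x))

    positions = x_start + dx_t * np.arange(n_x)
    d_map = SpatioTemporalMap(d_out, positions, t0=t_start, dt=dt_t, units=diam.units)
    p_map = SpatioTemporalMap(p_out, positions, t0=t_start, dt=dt_t, units=pres.units)
    # share the identical coordinate object between the two outputs
    p_map.sensor_positions = d_map.sensor_positions
    return d_map, p_map
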