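"""Synthetic peristalsis generator with known ground-truth states.

No public recordings exist for this kind of co-registered diameter/pressure
data, so testing end-to-end inference requires a generator that inverts the
emission semantics: a Markov chain over the twelve mechanical states drives
piecewise episodes of contraction, relaxation and quiescence, which are then
rendered into diameter and pressure traces.

Velocities are drawn per sample from the active state component: quiet
components give zero-mean normal noise, pos/neg components give half-normal
speeds with the configured scale (sign-correct by construction, one knob).
Diameter integrates its velocity and is clipped to ``[d_floor, d_ceiling]``
(an occlusion floor and a distension ceiling), with the realised velocity
re-derived after clipping.  Pressure integrates its velocity around a
baseline, with a slow sinusoidal drift added so that baseline removal has
something to do, plus measurement noise on both channels.

State sequences are kept physically coherent with both channels by
rejecting inadmissible transitions: occluded-component states are only
entered while the noise-free diameter sits near the floor, distended states
only well above it, and moving components (contraction/dilation, pressure
rise/fall) only while there is room left before the corresponding clip
bound.  Without this, truth labels would contradict the rendered
observations and recovery accuracy would be meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maps import SpatioTemporalMap, StateMap
from .states import (
    DIAMETER_COMPONENT_INDEX,
    DVEL_COMPONENT_INDEX,
    N_STATES,
    PVEL_COMPONENT_INDEX,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "admissible_states",
    "simulate_state_sequence",
    "render_observations",
    "simulate",
]

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a 10-minute 4 Hz recording over five 10 mm-spaced
    sensors: dwell times of ~12.5 s per state (gamma_true = 0.98 at 4 Hz),
    phasic contraction speeds well separated from quiet-band noise, and a
    4-14 mm diameter range.
    """

    n_sensors: int = 5
    n_samples: int = 2400
    dt: float = 0.25                    # s
    gamma_true: float = 0.98
    quiet_noise_dd: float = 0.1         # mm/s
    quiet_noise_dp: float = 0.8         # mmHg/s
    active_speed_dd: float = 1.5        # mm/s (half-normal scale)
    active_speed_dp: float = 8.0        # mmHg/s
    d_floor: float = 4.0                # mm
    d_ceiling: float = 14.0             # mm
    measurement_noise_d: float = 0.05   # mm
    measurement_noise_p: float = 0.2    # mmHg
    p_base: float = 10.0                # mmHg, resting pressure
    p_floor: float = 0.0                # mmHg
    p_ceiling: float = 60.0             # mmHg, peak phasic pressure
    drift_amplitude: float = 3.0        # mmHg, slow baseline drift
    drift_period: float = 120.0         # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_floor < self.d_ceiling:
            raise ValueError("d_floor must be below d_ceiling")
        if not (self.p_floor < self.p_ceiling and
                self.p_floor <= self.p_base <= self.p_ceiling):
            raise ValueError("need p_floor < p_ceiling with p_base inside")
        for name in ("quiet_noise_dd", "quiet_noise_dp", "active_speed_dd",
                     "active_speed_dp", "measurement_noise_d", "measurement_noise_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.gamma_true < 1.0):
            raise ValueError("gamma_true must lie in (0, 1)")
        if self.n_sensors < 1 or self.n_samples < 1:
            raise ValueError("need at least one sensor and one sample")


@dataclass
class GroundTruth:
    """A rendered synthetic recording together with its true state map."""

    states: StateMap
    diameter: SpatioTemporalMap
    pressure: SpatioTemporalMap
    nominal_diameter: np.ndarray = field(default=None)  # type: ignore[assignment]


def _streams(config: SimConfig) -> list[np.random.Generator]:
    """Independent per-sensor RNG streams: first half for the state chains,
    second half for rendering."""
    children = np.random.SeedSequence(config.seed).spawn(2 * config.n_sensors)
    return [np.random.default_rng(c) for c in children]


def admissible_states(d: float, p: float, config: SimConfig) -> np.ndarray:
    """Boolean mask over the 12 states admissible at diameter ``d``, pressure ``p``.

    Margins are fractions of each channel's range: occluded components only
    within 10% of the diameter floor, distended components above 40%
    dilation, and moving components (pos/neg rates on either channel) only
    with 3% of the range of travel left before the corresponding clip bound.
    Every (d, p) combination leaves a non-empty set.
    """
    d_span = config.d_ceiling - config.d_floor
    dilation = d - config.d_floor
    occ_ok = dilation <= 0.10 * d_span
    dis_ok = dilation >= 0.40 * d_span
    dneg_ok = dilation >= 0.03 * d_span
    dpos_ok = (config.d_ceiling - d) >= 0.03 * d_span
    p_span = config.p_ceiling - config.p_floor
    pneg_ok = (p - config.p_floor) >= 0.03 * p_span
    ppos_ok = (config.p_ceiling - p) >= 0.03 * p_span
    mask = np.ones(N_STATES, dtype=bool)
    mask &= np.where(DIAMETER_COMPONENT_INDEX == 2, occ_ok, True)   # occ
    mask &= np.where(DIAMETER_COMPONENT_INDEX == 1, dis_ok, True)   # dis
    mask &= np.where(DVEL_COMPONENT_INDEX == 2, dneg_ok, True)      # neg d_dot
    mask &= np.where(DVEL_COMPONENT_INDEX == 1, dpos_ok, True)      # pos d_dot
    mask &= np.where(PVEL_COMPONENT_INDEX == 2, pneg_ok, True)      # neg p_dot
    mask &= np.where(PVEL_COMPONENT_INDEX == 1, ppos_ok, True)      # pos p_dot
    return mask


def _draw_velocity(rng, comp_idx: int, quiet_noise: float, active_speed: float) -> float:
    if comp_idx == 0:
        return rng.normal(0.0, quiet_noise) if quiet_noise > 0 else 0.0
    mag = abs(rng.normal(0.0, active_speed)) if active_speed > 0 else 0.0
    return mag if comp_idx == 1 else -mag


def _simulate_chain(rng: np.random.Generator, config: SimConfig
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sensor's state chain with its noise-free diameter and pressure paths.

    States and both channels are sampled jointly: the admissibility gate at
    each step uses the traces actually produced by the velocities drawn for
    the states, so truth labels and the emitted observations can never
    contradict each other (an occluded truth state is guaranteed to sit near
    the floor of the *rendered* diameter, a pressure-rise state cannot be
    pinned at the pressure ceiling, and so on).
    """
    n = config.n_samples
    codes = np.empty(n, dtype=np.intp)
    true_d = np.empty(n)
    true_p = np.empty(n)
    d = rng.uniform(config.d_floor, config.d_ceiling)
    p = config.p_base
    mask = admissible_states(d, p, config)
    codes[0] = rng.choice(N_STATES, p=mask / mask.sum())
    true_d[0], true_p[0] = d, p
    gamma = config.gamma_true
    off = (1.0 - gamma) / (N_STATES - 1)
    for i in range(1, n):
        # base transition distribution restricted to the admissible set and
        # renormalised (equivalent in law to rejection resampling)
        probs = np.full(N_STATES, off)
        probs[codes[i - 1]] = gamma
        probs[~admissible_states(d, p, config)] = 0.0
        probs /= probs.sum()
        codes[i] = rng.choice(N_STATES, p=probs)
        vd = _draw_velocity(rng, DVEL_COMPONENT_INDEX[codes[i]],
                            config.quiet_noise_dd, config.active_speed_dd)
        d = float(np.clip(d + vd * config.dt, config.d_floor, config.d_ceiling))
        vp = _draw_velocity(rng, PVEL_COMPONENT_INDEX[codes[i]],
                            config.quiet_noise_dp, config.active_speed_dp)
        p = float(np.clip(p + vp * config.dt, config.p_floor, config.p_ceiling))
        true_d[i], true_p[i] = d, p
    return codes, true_d, true_p


def simulate_state_sequence(config: SimConfig, return_paths: bool = False):
    """Sample ground-truth state sequences for every sensor.

    The first state is uniform over the admissible set at a random starting
    diameter and the resting pressure; subsequent states follow the
    single-parameter transition model with ``gamma_true``, restricted at
    each step to states admissible at the current diameter and pressure.
    Deterministic given ``config.seed``.

    Returns
    -------
    ndarray, shape (n_sensors, n_samples)
        Integer state codes; with ``return_paths=True`` also the noise-free
        diameter and pressure paths that gated admissibility.
    """
    streams = _streams(config)
    codes = np.empty((config.n_sensors, config.n_samples), dtype=np.intp)
    true_d = np.empty((config.n_sensors, config.n_samples))
    true_p = np.empty((config.n_sensors, config.n_samples))
    for s in range(config.n_sensors):
        codes[s], true_d[s], true_p[s] = _simulate_chain(streams[s], config)
    if return_paths:
        return codes, true_d, true_p
    return codes


def _drift(n: int, config: SimConfig) -> np.ndarray:
    t = config.dt * np.arange(n)
    return config.drift_amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / config.drift_period))


def _render_pressure(rng, states_row: np.ndarray, config: SimConfig) -> np.ndarray:
    """Integrate per-state pressure rates from the resting pressure, clipped
    to the physiological band, plus slow baseline drift."""
    n = states_row.size
    pres = np.empty(n)
    p = config.p_base
    pres[0] = p
    for i in range(1, n):
        vp = _draw_velocity(rng, PVEL_COMPONENT_INDEX[states_row[i]],
                            config.quiet_noise_dp, config.active_speed_dp)
        p = float(np.clip(p + vp * config.dt, config.p_floor, config.p_ceiling))
        pres[i] = p
    return pres + _drift(n, config)


def _assemble(states: np.ndarray, diam: np.ndarray, pres: np.ndarray,
              streams, config: SimConfig) -> GroundTruth:
    """Add measurement noise and wrap the channels into GroundTruth maps."""
    n_sensors, n = states.shape
    diam = diam.copy()
    pres = pres.copy()
    for s in range(n_sensors):
        rng = streams[s]
        if config.measurement_noise_d > 0:
            diam[s] = np.clip(diam[s] + rng.normal(0.0, config.measurement_noise_d, n),
                              config.d_floor, config.d_ceiling)
        if config.measurement_noise_p > 0:
            pres[s] = pres[s] + rng.normal(0.0, config.measurement_noise_p, n)
    positions = 10.0 * np.arange(n_sensors)
    return GroundTruth(
        states=StateMap(states, positions.copy(), t0=0.0, dt=config.dt),
        diameter=SpatioTemporalMap(diam, positions.copy(), t0=0.0, dt=config.dt, units="mm"),
        pressure=SpatioTemporalMap(pres, positions.copy(), t0=0.0, dt=config.dt, units="mmHg"),
    )


def render_observations(states: np.ndarray, config: SimConfig) -> GroundTruth:
    """Render diameter and pressure maps for externally supplied state sequences.

    Per sample the two rates are drawn from the state's components, the
    diameter integrates its rate with clipping to ``[d_floor, d_ceiling]``
    (realised rate re-derived after clipping), the pressure integrates its
    rate from the resting value with clipping to ``[p_floor, p_ceiling]``
    plus a slow sinusoidal drift, and measurement noise is added to both
    recorded channels.

    The diameter here integrates fresh velocity draws, so occluded/distended
    components of an arbitrary input sequence are only honoured approximately;
    for sequences sampled jointly with their diameter use :func:`simulate`,
    whose truth labels are coherent with the emitted trace by construction.
    """
    states = np.asarray(states, dtype=np.intp)
    if states.ndim == 1:
        states = states[None, :]
    n_sensors, n = states.shape
    streams = _streams(config)[config.n_sensors:config.n_sensors + n_sensors]
    diam = np.empty((n_sensors, n))
    pres = np.empty((n_sensors, n))
    span = config.d_ceiling - config.d_floor
    for s in range(n_sensors):
        rng = streams[s]
        cd = DIAMETER_COMPONENT_INDEX[states[s, 0]]
        d = config.d_floor + (0.0 if cd == 2 else 0.6 * span if cd == 1 else 0.3 * span)
        diam[s, 0] = d
        for i in range(1, n):
            vd = _draw_velocity(rng, DVEL_COMPONENT_INDEX[states[s, i]],
                                config.quiet_noise_dd, config.active_speed_dd)
            d = float(np.clip(d + vd * config.dt, config.d_floor, config.d_ceiling))
            diam[s, i] = d
        pres[s] = _render_pressure(rng, states[s], config)
    return _assemble(states, diam, pres, streams, config)


def simulate(config: SimConfig) -> GroundTruth:
    """Generate a full synthetic recording with coherent ground truth.

    States and the noise-free diameter and pressure are sampled jointly (see
    :func:`simulate_state_sequence`), slow baseline drift is added to the
    pressure, and measurement noise is added to both recorded maps.
    Deterministic given ``config.seed``; the noise-free diameter is kept on
    the returned object as ``nominal_diameter``.
    """
    codes, true_d, true_p = simulate_state_sequence(config, return_paths=True)
    streams = _streams(config)[config.n_sensors:2 * config.n_sensors]
    pres = true_p + _drift(config.n_samples, config)[None, :]
    gt = _assemble(codes, true_d, pres, streams, config)
    gt.nominal_diameter = true_d
    return gt
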