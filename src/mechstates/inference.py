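"""Observation assembly and maximum a-posteriori state decoding.

Each sensor location along the gut is modelled as an independent hidden
Markov chain whose hidden variable is the mechanical state and whose
observation at sample ``i`` is the vector (d_i, d_dot_i, p_dot_i).  Rates are
estimated from the value sequences by central differences (one-sided at the
endpoints).  Transitions use a single smoothing parameter ``gamma``: the
probability of staying in the current state, with the remaining mass spread
uniformly over the other 11 states; the initial state is uniform.  The most
likely state sequence is found with the Viterbi algorithm in log space, with
ties broken towards the lowest canonical state index in both the per-step
maximisation and the final backtrace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emissions import log_emission_matrix
from .maps import SpatioTemporalMap, StateMap
from .params import ModelParams, ParameterError
from .states import N_STATES, STATES, MechanicalState

__all__ = [
    "ObservationSeries",
    "StateSequence",
    "estimate_derivatives",
    "transition_prob",
    "transition_matrix",
    "viterbi_decode",
    "infer_state_map",
    "path_log_score",
]


def estimate_derivatives(x, dt: float) -> np.ndarray:
    """Estimate the rate of change of a sampled sequence.

    Interior samples use central differences (x[i+1] - x[i-1]) / (2 dt); the
    first and last samples use one-sided differences over a single step.
    Exact for linear sequences, including at the endpoints.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 samples")
    if not dt > 0:
        raise ValueError("dt must be positive")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return v


@dataclass
class ObservationSeries:
    """Aligned (d, d_dot, p_dot) observation sequence for one sensor chain."""

    d: np.ndarray
    dd: np.ndarray
    dp: np.ndarray
    dt: float = 0.25

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.dd = np.asarray(self.dd, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        if not (self.d.shape == self.dd.shape == self.dp.shape) or self.d.ndim != 1:
            raise ValueError("d, dd and dp must be 1-D sequences of equal length")
        if self.d.size < 1:
            raise ValueError("observation sequence must be non-empty")

    @classmethod
    def from_traces(cls, d, p, dt: float) -> "ObservationSeries":
        """Build the observation sequence from raw diameter and pressure traces.

        Rates are computed once here (central differences) and cached on the
        returned object.
        """
        d = np.asarray(d, dtype=float)
        p = np.asarray(p, dtype=float)
        return cls(d=d, dd=estimate_derivatives(d, dt), dp=estimate_derivatives(p, dt), dt=dt)

    def __len__(self) -> int:
        return self.d.size


@dataclass
class StateSequence:
    """A decoded state path and its joint log weight."""

    states: list[MechanicalState]
    log_score: float
    codes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = np.array([s.value for s in self.states], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.states)


def transition_prob(current: MechanicalState, previous: MechanicalState,
                    gamma: float) -> float:
    """State-independent transition probability: gamma on the diagonal,
    (1 - gamma)/11 elsewhere."""
    if not (0.0 < gamma < 1.0):
        raise ParameterError(f"gamma must lie in (0, 1), got {gamma!r}")
    return gamma if current is previous or current == previous else (1.0 - gamma) / (N_STATES - 1)


def transition_matrix(gamma: float) -> np.ndarray:
    """The 12x12 transition matrix implied by ``gamma``; rows sum to 1."""
    if not (0.0 < gamma < 1.0):
        raise ParameterError(f"gamma must lie in (0, 1), got {gamma!r}")
    a = np.full((N_STATES, N_STATES), (1.0 - gamma) / (N_STATES - 1))
    np.fill_diagonal(a, gamma)
    return a


def path_log_score(obs: ObservationSeries, codes, params: ModelParams,
                   min_d: float | None = None) -> float:
    """Joint log weight of an arbitrary state path: uniform initial state,
    gamma transitions and the emission weights of the path."""
    codes = np.asarray(codes, dtype=np.intp)
    min_d = params.resolve_min_d(obs.d) if min_d is None else min_d
    logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=min_d)
    score = -np.log(N_STATES) + float(logb[np.arange(len(codes)), codes].sum())
    if len(codes) > 1:
        same = codes[1:] == codes[:-1]
        score += float(same.sum()) * np.log(params.gamma)
        score += float((~same).sum()) * np.log((1.0 - params.gamma) / (N_STATES - 1))
    return score


def _check_finite(obs: ObservationSeries) -> None:
    for name, arr in (("d", obs.d), ("d_dot", obs.dd), ("p_dot", obs.dp)):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-finite {name} observation at sample index {idx}")


def viterbi_decode(obs: ObservationSeries, params: ModelParams,
                   min_d: float | None = None) -> StateSequence:
    """Most likely mechanical state sequence for one sensor chain.

    Runs the Viterbi dynamic programme in log space over the 12 states, with
    a uniform initial distribution and the single-parameter transition model.
    The diameter floor ``min_d`` is resolved per chain (minimum of ``obs.d``)
    unless overridden on *params* or via the argument.

    Returns
    -------
    StateSequence
        The decoded path and its joint log weight (the log of the maximised
        joint factorisation evaluated along the path).
    """
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    _check_finite(obs)
    min_d = params.resolve_min_d(obs.d) if min_d is None else float(min_d)
    logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=min_d)
    codes, log_score = _viterbi_from_log_emissions(logb, params.gamma)
    return StateSequence(states=[STATES[c] for c in codes], log_score=log_score, codes=codes)


def _viterbi_from_log_emissions(logb: np.ndarray, gamma: float
                                ) -> tuple[np.ndarray, float]:
    """Core Viterbi dynamic programme over a (N, 12) log-emission matrix.

    Uniform initial state, single-parameter transitions; ties resolved
    towards the lowest canonical index in both the per-step maximisation
    (np.argmax returns the first maximiser) and the backtrace.
    """
    n = logb.shape[0]
    log_stay = np.log(gamma)
    log_move = np.log((1.0 - gamma) / (N_STATES - 1))
    loga = np.full((N_STATES, N_STATES), log_move)
    np.fill_diagonal(loga, log_stay)

    delta = logb[0] - np.log(N_STATES)
    ptr = np.zeros((n, N_STATES), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + loga          # (from, to)
        ptr[t] = np.argmax(cand, axis=0)      # first max -> lowest canonical index
        delta = cand[ptr[t], np.arange(N_STATES)] + logb[t]

    codes = np.empty(n, dtype=np.intp)
    codes[-1] = int(np.argmax(delta))
    log_score = float(delta[codes[-1]])
    for t in range(n - 1, 0, -1):
        codes[t - 1] = ptr[t, codes[t]]
    return codes, log_score


def infer_state_map(diameter_map: SpatioTemporalMap, pressure_map: SpatioTemporalMap,
                    params: ModelParams) -> StateMap:
    """Decode every sensor chain of a pair of aligned maps independently.

    Row ``r`` of the result is :func:`viterbi_decode` applied to the
    observation series built from row ``r`` of the diameter and pressure
    maps; rows do not interact, so the output is identical under any row
    evaluation order.
    """
    if diameter_map.values.shape != pressure_map.values.shape:
        raise ValueError(
            f"diameter and pressure maps differ in shape: "
            f"{diameter_map.values.shape} vs {pressure_map.values.shape}"
        )
    if not diameter_map.same_grid(pressure_map):
        raise ValueError("diameter and pressure maps are not on the same grid")
    dt = diameter_map.dt
    codes = np.empty(diameter_map.values.shape, dtype=np.intp)
    scores = np.empty(diameter_map.n_sensors)
    for r in range(diameter_map.n_sensors):
        obs = ObservationSeries.from_traces(diameter_map.values[r], pressure_map.values[r], dt)
        seq = viterbi_decode(obs, params)
        codes[r] = seq.codes
        scores[r] = seq.log_score
    return StateMap(
        codes=codes,
        sensor_positions=diameter_map.sensor_positions.copy(),
        t0=diameter_map.t0,
        dt=dt,
        log_scores=scores,
    )
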