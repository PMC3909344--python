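"""Simplified-state mapping, classification error and sensitivity analysis.

For comparing two decodings the twelve states collapse to three classes:
active contraction ``ac`` = {oimc, itc, atc}, active relaxation ``ar`` =
{itr, atr}, and the passive class ``pas`` holding the remaining seven states
(named ``pas`` rather than the literature's overloaded "ps", which is also a
state label).  The classification error between a reference and a comparison
decoding is

    epsilon = sum_ji alpha_ji [s_ji != s'_ji] / sum_ji alpha_ji

where alpha_ji is one iff the simplified states of both decodings at sensor
``j``, sample ``i`` are active.  Parameter sensitivity is assessed by
decoding once with reference parameter values (treated as ground truth) and
re-decoding while varying one parameter at a time over its analysis range.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .inference import infer_state_map
from .maps import SpatioTemporalMap
from .params import ModelParams, ParameterError
from .states import N_STATES, STATES, MechanicalState

__all__ = [
    "SimplifiedState",
    "AllPassiveError",
    "simplify_state",
    "simplify_codes",
    "classification_error",
    "SensitivityResult",
    "TABLE_RANGES",
    "default_sweep_ranges",
    "parameter_sweep",
    "TransitionCounts",
    "count_transitions",
]


class SimplifiedState(Enum):
    """Three-class summary of the mechanical states."""

    PAS = 0
    AC = 1
    AR = 2

    @property
    def label(self) -> str:
        return self.name.lower()


_AC = {MechanicalState.OIMC, MechanicalState.ITC, MechanicalState.ATC}
_AR = {MechanicalState.ITR, MechanicalState.ATR}

# code -> simplified code lookup, canonical order
SIMPLIFY_LOOKUP = np.array(
    [1 if s in _AC else 2 if s in _AR else 0 for s in STATES], dtype=np.intp
)


def simplify_state(s: MechanicalState) -> SimplifiedState:
    """Map a mechanical state to its simplified class (total mapping)."""
    return SimplifiedState(int(SIMPLIFY_LOOKUP[s.value]))


def simplify_codes(codes) -> np.ndarray:
    """Vectorised simplification of an integer-coded state array."""
    return SIMPLIFY_LOOKUP[np.asarray(codes, dtype=np.intp)]


class AllPassiveError(ValueError):
    """No sample is active in both maps, so the error ratio is undefined."""


def _codes_of(m) -> np.ndarray:
    return np.asarray(getattr(m, "codes", m), dtype=np.intp)


def classification_error(reference, comparison) -> float:
    """Active-state disagreement ratio epsilon between two state maps.

    Only positions where *both* simplified states are active (ac or ar)
    enter the denominator; the numerator counts those positions where the
    two active classes differ.  Symmetric in its arguments.

    Raises
    ------
    AllPassiveError
        If no position is active in both maps (zero denominator).
    """
    ref = _codes_of(reference)
    cmp_ = _codes_of(comparison)
    if ref.shape != cmp_.shape:
        raise ValueError(f"state maps differ in shape: {ref.shape} vs {cmp_.shape}")
    s_ref = simplify_codes(ref)
    s_cmp = simplify_codes(cmp_)
    alpha = (s_ref != 0) & (s_cmp != 0)
    denom = int(alpha.sum())
    if denom == 0:
        raise AllPassiveError(
            "classification error is undefined: no sample is active in both maps"
        )
    return float((alpha & (s_ref != s_cmp)).sum() / denom)


# Analysis ranges for the one-at-a-time sensitivity sweep (min, max).
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "mu_d": (0.0, 7.5),        # mm
    "sigma_d": (0.0, 1.2),     # mm
    "sigma_ddot": (0.0, 1.2),  # mm/s
    "sigma_pdot": (0.0, 9.0),  # mmHg/s
    "gamma": (0.255, 0.99),
}

_EPS_CLAMP = 1e-6

_DOMAIN = {
    "mu_d": (0.0, np.inf),
    "sigma_d": (_EPS_CLAMP, np.inf),
    "sigma_ddot": (_EPS_CLAMP, np.inf),
    "sigma_pdot": (_EPS_CLAMP, np.inf),
    "gamma": (_EPS_CLAMP, 1.0 - _EPS_CLAMP),
}


def default_sweep_ranges(reference: ModelParams, n_points: int = 16
                         ) -> dict[str, np.ndarray]:
    """Evenly spaced sweep grids over the published analysis ranges.

    Endpoints outside the open parameter domain (sigma = 0, gamma in {0, 1})
    are clamped inward by 1e-6; grid values numerically indistinguishable
    from the reference value snap to it exactly.
    """
    ranges = {}
    for name, (lo, hi) in TABLE_RANGES.items():
        grid = np.linspace(lo, hi, n_points)
        dlo, dhi = _DOMAIN[name]
        grid = np.clip(grid, dlo, dhi)
        ref = getattr(reference, name)
        grid[np.isclose(grid, ref, rtol=1e-9, atol=1e-12)] = ref
        ranges[name] = grid
    return ranges


@dataclass
class SensitivityResult:
    """Classification error over one parameter's sweep grid."""

    parameter: str
    values: np.ndarray
    epsilon: np.ndarray
    reference_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.parameter, "value": self.values, "epsilon": self.epsilon}
        )


def parameter_sweep(diam: SpatioTemporalMap, pres: SpatioTemporalMap,
                    reference_params: ModelParams,
                    ranges: dict[str, np.ndarray] | None = None,
                    n_points: int = 16) -> dict[str, SensitivityResult]:
    """One-at-a-time parameter sensitivity of the decoded state map.

    Decodes once with *reference_params* (the reference classification,
    treated as ground truth), then re-decodes with each swept value
    substituted for one parameter at a time and reports the classification
    error epsilon against the reference.  ``min_d`` is data-derived per
    sensor chain and therefore identical in every decode; it is not swept.
    """
    if ranges is None:
        ranges = default_sweep_ranges(reference_params, n_points)
    for name, grid in ranges.items():
        if name not in _DOMAIN:
            raise ParameterError(f"unknown sweep parameter {name!r}")
        dlo, dhi = _DOMAIN[name]
        grid = np.asarray(grid, dtype=float)
        if np.any(grid < dlo) or np.any(grid > dhi):
            raise ParameterError(f"sweep range for {name} leaves the admissible domain")
        ranges[name] = grid
    reference_map = infer_state_map(diam, pres, reference_params)
    results = {}
    for name, grid in ranges.items():
        ref_value = getattr(reference_params, name)
        eps = np.empty(grid.size)
        for k, value in enumerate(grid):
            if value == ref_value:
                eps[k] = 0.0
                continue
            varied = reference_params.replace(**{name: float(value)})
            comparison = infer_state_map(diam, pres, varied)
            eps[k] = classification_error(reference_map, comparison)
        results[name] = SensitivityResult(name, grid, eps, ref_value)
    return results


@dataclass
class TransitionCounts:
    """12x12 matrix of observed state-transition occurrences."""

    counts: np.ndarray  # from-state rows, to-state columns

    def to_frame(self) -> pd.DataFrame:
        labels = [s.label for s in STATES]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_transitions(state_map) -> TransitionCounts:
    """Count ordered state pairs (s_{i-1}, s_i) within each sensor row.

    Rows are never concatenated, so the total count is the sum over rows of
    (row length - 1).
    """
    codes = _codes_of(state_map)
    if codes.ndim == 1:
        codes = codes[None, :]
    if codes.size == 0:
        raise ValueError("state map is empty")
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for row in codes:
        if row.size > 1:
            np.add.at(counts, (row[:-1], row[1:]), 1)
    return TransitionCounts(counts)
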