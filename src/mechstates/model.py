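"""Model/Results interface over the mechanical-state HMM.

`MechanicalStateHMM` holds a pair of aligned diameter and pressure maps
together with the model parameters; `fit()` performs maximum a-posteriori
Viterbi decoding of every sensor chain and returns a
`MechanicalStateResults` object carrying the decoded state map, per-chain
log scores, summaries, sensitivity analysis and plotting.

Example
-------
>>> from mechstates import MechanicalStateHMM, ModelParams, simulate, SimConfig
>>> gt = simulate(SimConfig(seed=1))
>>> res = MechanicalStateHMM(gt.diameter, gt.pressure, ModelParams()).fit()
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    SensitivityResult,
    TransitionCounts,
    classification_error,
    count_transitions,
    parameter_sweep,
    simplify_codes,
)
from .inference import infer_state_map
from .maps import (
    SpatioTemporalMap,
    StateMap,
    read_map,
    write_state_map,
)
from .params import ModelParams
from .states import STATES

__all__ = ["MechanicalStateHMM", "MechanicalStateResults"]


def _as_map(x, dt: float, units: str) -> SpatioTemporalMap:
    if isinstance(x, SpatioTemporalMap):
        return x
    values = np.asarray(x, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    positions = 10.0 * np.arange(values.shape[0])
    return SpatioTemporalMap(values, positions, t0=0.0, dt=dt, units=units)


class MechanicalStateHMM:
    """Hidden Markov model of gut-muscle mechanical states.

    Parameters
    ----------
    diameter, pressure : SpatioTemporalMap or array_like
        Co-registered sensors x time maps on a common grid (mm and mmHg).
        Bare arrays are wrapped assuming 10 mm sensor spacing and the
        sampling interval from *params*.
    params : ModelParams, optional
        Emission/transition parameters; defaults to the published values.
    """

    def __init__(self, diameter, pressure, params: ModelParams | None = None):
        self.params = params or ModelParams()
        self.diameter = _as_map(diameter, self.params.dt, "mm")
        self.pressure = _as_map(pressure, self.params.dt, "mmHg")
        if self.diameter.values.shape != self.pressure.values.shape:
            raise ValueError("diameter and pressure maps must share a shape")
        if not self.diameter.same_grid(self.pressure):
            raise ValueError("diameter and pressure maps must share a grid")

    @classmethod
    def from_tsv(cls, diameter_path, pressure_path,
                 params: ModelParams | None = None) -> "MechanicalStateHMM":
        """Build the model from two map files written in the package's TSV format."""
        return cls(read_map(diameter_path), read_map(pressure_path), params)

    @property
    def n_sensors(self) -> int:
        return self.diameter.n_sensors

    @property
    def n_samples(self) -> int:
        return self.diameter.n_samples

    def fit(self) -> "MechanicalStateResults":
        """Decode every sensor chain (Viterbi MAP) and return the results."""
        state_map = infer_state_map(self.diameter, self.pressure, self.params)
        return MechanicalStateResults(self, state_map)


class MechanicalStateResults:
    """Decoded mechanical-state map and derived diagnostics."""

    def __init__(self, model: MechanicalStateHMM, state_map: StateMap):
        self.model = model
        self.params = model.params
        self.state_map = state_map
        self.log_scores = state_map.log_scores

    # -- derived quantities -------------------------------------------------

    def simplified_codes(self) -> np.ndarray:
        """Simplified 3-class codes (0=pas, 1=ac, 2=ar) per sensor and sample."""
        return simplify_codes(self.state_map.codes)

    def occupancy(self) -> pd.Series:
        """Fraction of samples spent in each of the twelve states."""
        counts = np.bincount(self.state_map.codes.ravel(), minlength=12)
        return pd.Series(counts / counts.sum(), index=[s.label for s in STATES])

    def transition_counts(self) -> TransitionCounts:
        """Observed transition occurrences between consecutive samples."""
        return count_transitions(self.state_map)

    def classification_error(self, other) -> float:
        """Active-state disagreement epsilon against another decoding."""
        other_map = getattr(other, "state_map", other)
        return classification_error(self.state_map, other_map)

    def sensitivity(self, ranges=None, n_points: int = 16
                    ) -> dict[str, SensitivityResult]:
        """One-at-a-time parameter sweep using this fit's parameters as reference."""
        return parameter_sweep(self.model.diameter, self.model.pressure,
                               self.params, ranges=ranges, n_points=n_points)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the decoding."""
        occ = self.occupancy()
        simp = self.simplified_codes()
        frac = lambda c: (simp == c).mean()  # noqa: E731
        p = self.params
        lines = [
            "         Mechanical state decoding",
            "=" * 50,
            f"Sensors:               {self.state_map.n_sensors}",
            f"Samples per sensor:    {self.state_map.n_samples}   (dt = {p.dt:g} s)",
            f"Parameters:            mu_d={p.mu_d:g} mm  sigma_d={p.sigma_d:g} mm",
            f"                       sigma_ddot={p.sigma_ddot:g} mm/s  "
            f"sigma_pdot={p.sigma_pdot:g} mmHg/s  gamma={p.gamma:g}",
            f"min_d:                 {'per-chain minimum' if p.min_d is None else f'{p.min_d:g} mm (global)'}",
            f"Total log score:       {float(np.sum(self.log_scores)):.3f}",
            "-" * 50,
            "State occupancy:",
        ]
        for label, value in occ.items():
            lines.append(f"    {label:<5s} {value:8.4f}")
        lines += [
            "-" * 50,
            f"Simplified occupancy:  ac={frac(1):.4f}  ar={frac(2):.4f}  pas={frac(0):.4f}",
            "=" * 50,
        ]
        return "\n".join(lines)

    def plot(self, mode: str = "full", path=None, scale: int = 4):
        """Render the decoded map as an RGB image (see plotting module)."""
        from .plotting import render_state_map

        return render_state_map(self.state_map, mode=mode, path=path, scale=scale)

    def save(self, prefix) -> dict[str, str]:
        """Write the state map, simplified map and transition counts as TSV.

        Returns a mapping from artifact name to the path written.
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {}
        states_path = f"{prefix}_states.tsv"
        write_state_map(self.state_map, states_path)
        paths["states"] = states_path
        simp = StateMap(self.simplified_codes(), self.state_map.sensor_positions,
                        t0=self.state_map.t0, dt=self.state_map.dt)
        simp_path = f"{prefix}_states_simplified.tsv"
        write_state_map(simp, simp_path, simplified=True)
        paths["simplified"] = simp_path
        trans_path = f"{prefix}_transitions.tsv"
        self.transition_counts().to_frame().to_csv(trans_path, sep="\t")
        paths["transitions"] = trans_path
        return paths
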