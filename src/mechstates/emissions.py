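"""State-component probability mass functions and emission weights.

Each observation element (diameter ``d``, diameter rate ``d_dot``, pressure
rate ``p_dot``) is scored against its three possible state components with a
normalised PMF built from a normal bell at zero (quiet) and normal CDF tails.

For a velocity element ``v`` with width ``sigma_v``::

    f(quiet | v) = Z_v * exp(-v^2 / (2 sigma_v^2))
    f(pos   | v) = Z_v * Phi( v / sigma_v)
    f(neg   | v) = Z_v * Phi(-v / sigma_v)
    Z_v          = 1 / (exp(-v^2 / (2 sigma_v^2)) + 1)

and for the diameter, with dilation ``d - min_d`` and threshold ``mu_d``::

    f(any | d) = Z_d
    f(dis | d) = Z_d * Phi((d - min_d - mu_d) / sigma_d)
    f(occ | d) = Z_d * Phi((mu_d - d + min_d) / sigma_d)
    Z_d        = 1/2

where ``Phi`` is the standard normal CDF.  Both triples sum to one for every
observation.

The joint emission weight of a state is the product of its three component
PMFs evaluated at the observation.  This uses the practical approximation
``f(o | c_o) ~ f(c_o | o)``, i.e. the component priors ``f(c_o)`` and the
observation prior ``f(o)`` are treated as constants and dropped; the weight
is therefore *not* a normalised density over observations — only relative
sizes across states matter, which is all Viterbi decoding needs.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import log_ndtr, ndtr

from .params import ModelParams, ParameterError
from .states import (
    DIAMETER_COMPONENT_INDEX,
    DVEL_COMPONENT_INDEX,
    PVEL_COMPONENT_INDEX,
    MechanicalState,
)

__all__ = [
    "Observation",
    "velocity_component_pmf",
    "velocity_component_logpmf",
    "diameter_component_pmf",
    "diameter_component_logpmf",
    "emission_weight",
    "log_emission_matrix",
    "estimate_component_priors",
]


class Observation(NamedTuple):
    """A single aligned observation: diameter (mm) and the two rates."""

    d: float       # mm
    dd: float      # mm/s
    dp: float      # mmHg/s


def _check_sigma(sigma: float, name: str = "sigma_v") -> float:
    sigma = float(sigma)
    if not (np.isfinite(sigma) and sigma > 0):
        raise ParameterError(f"{name} must be positive and finite, got {sigma!r}")
    return sigma


def velocity_component_pmf(v, sigma_v):
    """PMF triple (quiet, pos, neg) for a velocity observation.

    Parameters
    ----------
    v : float or array_like
        Observed rate of change (mm/s or mmHg/s).
    sigma_v : float
        Width of the quiet band, in the same units as ``v``.

    Returns
    -------
    ndarray
        Probabilities stacked on the last axis in the order
        (quiet, pos, neg); sums to 1 along that axis.
    """
    sigma_v = _check_sigma(sigma_v)
    v = np.asarray(v, dtype=float)
    bell = np.exp(-(v**2) / (2.0 * sigma_v**2))
    z = 1.0 / (bell + 1.0)
    return np.stack([z * bell, z * ndtr(v / sigma_v), z * ndtr(-v / sigma_v)], axis=-1)


def velocity_component_logpmf(v, sigma_v):
    """Log of :func:`velocity_component_pmf`, stable for extreme ``v/sigma_v``."""
    sigma_v = _check_sigma(sigma_v)
    v = np.asarray(v, dtype=float)
    log_bell = -(v**2) / (2.0 * sigma_v**2)
    log_z = -np.logaddexp(log_bell, 0.0)
    return np.stack(
        [log_bell + log_z, log_ndtr(v / sigma_v) + log_z, log_ndtr(-v / sigma_v) + log_z],
        axis=-1,
    )


def diameter_component_pmf(d, params: ModelParams, min_d: float | None = None):
    """PMF triple (any, dis, occ) for a diameter observation.

    ``min_d`` must either be set on *params* or passed explicitly (it is a
    data-derived per-chain quantity, not a tuned constant).
    """
    min_d = params.min_d if min_d is None else float(min_d)
    if min_d is None:
        raise ParameterError("min_d is unresolved: set params.min_d or pass min_d")
    d = np.asarray(d, dtype=float)
    x = (d - min_d - params.mu_d) / params.sigma_d
    return np.stack([np.full_like(d, 0.5), 0.5 * ndtr(x), 0.5 * ndtr(-x)], axis=-1)


def diameter_component_logpmf(d, params: ModelParams, min_d: float | None = None):
    """Log of :func:`diameter_component_pmf`."""
    min_d = params.min_d if min_d is None else float(min_d)
    if min_d is None:
        raise ParameterError("min_d is unresolved: set params.min_d or pass min_d")
    d = np.asarray(d, dtype=float)
    x = (d - min_d - params.mu_d) / params.sigma_d
    log_half = np.log(0.5)
    return np.stack(
        [np.full_like(d, log_half), log_ndtr(x) + log_half, log_ndtr(-x) + log_half],
        axis=-1,
    )


def emission_weight(o, state: MechanicalState, params: ModelParams,
                    min_d: float | None = None) -> float:
    """Joint emission weight f(d|c_d) * f(d_dot|c_dd) * f(p_dot|c_dp) of a state.

    The value lies in (0, 1] but is not normalised as a density over
    observations (see module docstring).
    """
    o = Observation(*o)
    if not all(np.isfinite(o)):
        raise ValueError(f"observation contains non-finite values: {o}")
    if o.d < 0:
        raise ValueError(f"diameter must be non-negative, got {o.d}")
    fd = diameter_component_pmf(o.d, params, min_d=min_d)
    fdd = velocity_component_pmf(o.dd, params.sigma_ddot)
    fdp = velocity_component_pmf(o.dp, params.sigma_pdot)
    i_d, i_dd, i_dp = (
        DIAMETER_COMPONENT_INDEX[state.value],
        DVEL_COMPONENT_INDEX[state.value],
        PVEL_COMPONENT_INDEX[state.value],
    )
    return float(fd[i_d] * fdd[i_dd] * fdp[i_dp])


def log_emission_matrix(d, dd, dp, params: ModelParams, min_d: float | None = None):
    """Log emission weights for a whole chain.

    Parameters
    ----------
    d, dd, dp : array_like, shape (N,)
        Diameter, diameter-rate and pressure-rate sequences.

    Returns
    -------
    ndarray, shape (N, 12)
        ``out[i, s]`` is the log emission weight of state ``s`` at sample
        ``i``, states in canonical order.
    """
    ld = diameter_component_logpmf(d, params, min_d=min_d)      # (N, 3)
    ldd = velocity_component_logpmf(dd, params.sigma_ddot)      # (N, 3)
    ldp = velocity_component_logpmf(dp, params.sigma_pdot)      # (N, 3)
    return (
        ld[..., DIAMETER_COMPONENT_INDEX]
        + ldd[..., DVEL_COMPONENT_INDEX]
        + ldp[..., PVEL_COMPONENT_INDEX]
    )


def estimate_component_priors(observations, params: ModelParams,
                              min_d: float | None = None) -> dict:
    """Empirical state-component priors f(c_o) for each observation element.

    The prior is the marginal f(c_o) = integral f(c_o|o) f(o) do, approximated
    by the sample average of f(c_o | o_i) over the supplied observations
    (equivalent to kernel-density estimation of f(o) followed by
    marginalisation, in the large-sample limit).  For each element the three
    priors sum to one.

    Parameters
    ----------
    observations : sequence of Observation-like triples, or an object with
        ``d``, ``dd``, ``dp`` array attributes.

    Returns
    -------
    dict
        ``{"d": {"any": ., "dis": ., "occ": .}, "d_dot": {"quiet": ., "pos": .,
        "neg": .}, "p_dot": {...}}``
    """
    if hasattr(observations, "d") and hasattr(observations, "dd"):
        d = np.asarray(observations.d, dtype=float)
        dd = np.asarray(observations.dd, dtype=float)
        dp = np.asarray(observations.dp, dtype=float)
    else:
        arr = np.asarray([tuple(o) for o in observations], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("observations must be a sequence of (d, dd, dp) triples")
        d, dd, dp = arr.T
    if d.size < 2:
        raise ValueError("at least 2 observations are required to estimate priors")
    if min_d is None and params.min_d is None:
        min_d = float(np.min(d))
    fd = diameter_component_pmf(d, params, min_d=min_d).mean(axis=0)
    fdd = velocity_component_pmf(dd, params.sigma_ddot).mean(axis=0)
    fdp = velocity_component_pmf(dp, params.sigma_pdot).mean(axis=0)
    return {
        "d": {"any": float(fd[0]), "dis": float(fd[1]), "occ": float(fd[2])},
        "d_dot": {"quiet": float(fdd[0]), "pos": float(fdd[1]), "neg": float(fdd[2])},
        "p_dot": {"quiet": float(fdp[0]), "pos": float(fdp[1]), "neg": float(fdp[2])},
    }
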