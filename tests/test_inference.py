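"""Decoding: derivatives, transitions, Viterbi against brute-force enumeration."""

import itertools

import numpy as np
import pytest

from mechstates import (
    MechanicalState,
    ModelParams,
    ObservationSeries,
    ParameterError,
    estimate_derivatives,
    infer_state_map,
    transition_matrix,
    transition_prob,
    viterbi_decode,
)
from mechstates.emissions import log_emission_matrix
from mechstates.inference import _viterbi_from_log_emissions, path_log_score
from mechstates.maps import SpatioTemporalMap

from conftest import random_observations


def brute_force_decode(logb: np.ndarray, gamma: float):
    """Exhaustive maximisation over all 12^N paths (oracle, N small).

    Scores every path by direct evaluation of the joint log factorisation:
    uniform initial state, gamma transitions, per-sample log emissions.
    Ties resolved to the lexicographically smallest path, which matches
    canonical-order tie-breaking.
    """
    n, k = logb.shape
    paths = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.intp)
    scores = np.full(paths.shape[0], -np.log(k))
    scores += logb[np.arange(n), paths].sum(axis=1)
    if n > 1:
        same = paths[:, 1:] == paths[:, :-1]
        scores += same.sum(axis=1) * np.log(gamma)
        scores += (~same).sum(axis=1) * np.log((1 - gamma) / (k - 1))
    best = np.argmax(scores)  # product() yields lexicographic order; first max wins
    return paths[best], float(scores[best])


def make_obs(rng, n, params):
    d, dd, dp = random_observations(rng, n, params)
    return ObservationSeries(d=d, dd=dd, dp=dp, dt=params.dt)


# ---------------------------------------------------------------- derivatives

def test_derivatives_constant_and_linear():
    assert np.all(estimate_derivatives(np.full(9, 3.7), 0.25) == 0)
    t = 0.25 * np.arange(15)
    np.testing.assert_allclose(estimate_derivatives(2.0 + 1.4 * t, 0.25), 1.4,
                               rtol=1e-12)


def test_derivatives_worked_example():
    np.testing.assert_allclose(
        estimate_derivatives([0.0, 1.0, 3.0], 0.25), [4.0, 6.0, 8.0]
    )


def test_derivatives_rejects_short_or_bad_input():
    with pytest.raises(ValueError):
        estimate_derivatives([1.0], 0.25)
    with pytest.raises(ValueError):
        estimate_derivatives([1.0, 2.0], 0.0)


# ---------------------------------------------------------------- transitions

def test_transition_probabilities():
    a, b = MechanicalState.OQ, MechanicalState.ITC
    assert transition_prob(a, a, 0.5) == 0.5
    assert transition_prob(b, a, 0.5) == pytest.approx(0.5 / 11)
    m = transition_matrix(1 / 12)
    np.testing.assert_allclose(m, 1 / 12)


@pytest.mark.parametrize("gamma", [0.01, 1 / 12, 0.5, 0.98])
def test_transition_matrix_rows_sum_to_one(gamma):
    np.testing.assert_allclose(transition_matrix(gamma).sum(axis=1), 1.0, rtol=1e-12)


@pytest.mark.parametrize("gamma", [0.0, 1.0, -0.1, 1.5])
def test_transition_gamma_domain(gamma):
    with pytest.raises(ParameterError):
        transition_prob(MechanicalState.OQ, MechanicalState.OQ, gamma)


# ---------------------------------------------------------------- viterbi

def test_single_sample_decodes_to_emission_argmax(rng):
    params = ModelParams()
    for _ in range(10):
        obs = make_obs(rng, 1, params)
        seq = viterbi_decode(obs, params)
        logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params,
                                   min_d=float(obs.d.min()))
        assert seq.codes[0] == int(np.argmax(logb[0]))


def test_viterbi_matches_brute_force_enumeration(rng):
    """Decoded path and log score equal exhaustive search over 12^N paths."""
    for trial in range(30):
        params = ModelParams(gamma=float(rng.uniform(0.1, 0.95)))
        n = int(rng.integers(1, 5))
        obs = make_obs(rng, n, params)
        min_d = float(obs.d.min())
        seq = viterbi_decode(obs, params)
        logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=min_d)
        ref_path, ref_score = brute_force_decode(logb, params.gamma)
        np.testing.assert_array_equal(seq.codes, ref_path)
        assert seq.log_score == pytest.approx(ref_score, abs=1e-9)


def test_viterbi_agrees_with_independent_hmm_library(rng):
    """Cross-check against hmmlearn's compiled Viterbi kernel."""
    from hmmlearn import _hmmc

    params = ModelParams()
    obs = make_obs(rng, 200, params)
    logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=float(obs.d.min()))
    start = np.full(12, 1 / 12)
    ref_score, ref_path = _hmmc.viterbi(start, transition_matrix(params.gamma), logb)
    seq = viterbi_decode(obs, params)
    np.testing.assert_array_equal(seq.codes, ref_path)
    assert seq.log_score == pytest.approx(float(ref_score), rel=1e-9)


def test_decoded_score_equals_path_factorisation(rng):
    params = ModelParams()
    obs = make_obs(rng, 50, params)
    seq = viterbi_decode(obs, params)
    assert seq.log_score == pytest.approx(path_log_score(obs, seq.codes, params),
                                          abs=1e-8)


def test_constant_occluded_quiet_input_decodes_to_oq():
    params = ModelParams()
    obs = ObservationSeries(d=np.full(20, 4.0), dd=np.zeros(20), dp=np.zeros(20))
    seq = viterbi_decode(obs, params, min_d=4.0)
    assert all(s is MechanicalState.OQ for s in seq.states)


def test_independence_limit_equals_per_sample_argmax(rng):
    """At gamma = 1/12 adjacent samples decouple: path = emission argmax."""
    params = ModelParams(gamma=1 / 12)
    for _ in range(10):
        obs = make_obs(rng, 100, params)
        min_d = float(obs.d.min())
        logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=min_d)
        seq = viterbi_decode(obs, params)
        np.testing.assert_array_equal(seq.codes, np.argmax(logb, axis=1))


def test_switch_count_nonincreasing_in_gamma(rng):
    """More smoothing never adds state changes (fixed tie-breaking)."""
    base = ModelParams()
    for _ in range(5):
        obs = make_obs(rng, 120, base)
        switches = []
        for gamma in [1 / 12 + 0.001, 0.2, 0.4, 0.6, 0.8, 0.95, 0.995]:
            seq = viterbi_decode(obs, base.replace(gamma=gamma))
            switches.append(int((seq.codes[1:] != seq.codes[:-1]).sum()))
        assert all(a >= b for a, b in zip(switches, switches[1:]))


def test_per_sample_emission_rescaling_leaves_path_unchanged(rng):
    """Multiplying all emission weights at one sample by a constant cannot
    change the decoded path (only relative sizes across states matter)."""
    params = ModelParams()
    obs = make_obs(rng, 80, params)
    logb = log_emission_matrix(obs.d, obs.dd, obs.dp, params, min_d=float(obs.d.min()))
    path, _ = _viterbi_from_log_emissions(logb, params.gamma)
    offsets = rng.normal(0.0, 5.0, logb.shape[0])
    path2, _ = _viterbi_from_log_emissions(logb + offsets[:, None], params.gamma)
    np.testing.assert_array_equal(path, path2)


def test_viterbi_input_validation():
    params = ModelParams()
    with pytest.raises(ValueError):
        ObservationSeries(d=np.array([]), dd=np.array([]), dp=np.array([]))
    obs = ObservationSeries(d=np.array([4.0, np.nan, 5.0]), dd=np.zeros(3),
                            dp=np.zeros(3))
    with pytest.raises(ValueError, match="index 1"):
        viterbi_decode(obs, params)


# ---------------------------------------------------------------- state maps

def _random_maps(rng, n_sensors=3, n=40):
    params = ModelParams()
    d = rng.uniform(4, 14, (n_sensors, n))
    p = rng.uniform(0, 30, (n_sensors, n))
    pos = 10.0 * np.arange(n_sensors)
    return (SpatioTemporalMap(d, pos, dt=params.dt, units="mm"),
            SpatioTemporalMap(p, pos, dt=params.dt, units="mmHg"), params)


def test_single_row_map_matches_viterbi_decode(rng):
    diam, pres, params = _random_maps(rng, n_sensors=1)
    sm = infer_state_map(diam, pres, params)
    obs = ObservationSeries.from_traces(diam.values[0], pres.values[0], params.dt)
    np.testing.assert_array_equal(sm.codes[0], viterbi_decode(obs, params).codes)


def test_row_permutation_equivariance(rng):
    diam, pres, params = _random_maps(rng, n_sensors=4)
    sm = infer_state_map(diam, pres, params)
    perm = np.array([2, 0, 3, 1])
    # rows are independent chains: permuting inputs permutes outputs identically
    diam_p = SpatioTemporalMap(diam.values[perm], diam.sensor_positions,
                               dt=diam.dt, units="mm")
    pres_p = SpatioTemporalMap(pres.values[perm], pres.sensor_positions,
                               dt=pres.dt, units="mmHg")
    sm_p = infer_state_map(diam_p, pres_p, params)
    np.testing.assert_array_equal(sm_p.codes, sm.codes[perm])


def test_shape_mismatch_rejected(rng):
    diam, pres, params = _random_maps(rng)
    bad = SpatioTemporalMap(pres.values[:, :-1], pres.sensor_positions,
                            dt=pres.dt, units="mmHg")
    with pytest.raises(ValueError, match="shape"):
        infer_state_map(diam, bad, params)


def test_observation_series_from_traces_caches_central_differences(rng):
    d = rng.uniform(4, 14, 30)
    p = rng.uniform(0, 30, 30)
    obs = ObservationSeries.from_traces(d, p, 0.25)
    np.testing.assert_array_equal(obs.dd, estimate_derivatives(d, 0.25))
    np.testing.assert_array_equal(obs.dp, estimate_derivatives(p, 0.25))
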