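"""Emission model: component PMFs, joint weights and empirical priors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mechstates import (
    MechanicalState,
    ModelParams,
    ParameterError,
    STATES,
    diameter_component_pmf,
    emission_weight,
    estimate_component_priors,
    velocity_component_pmf,
)
from mechstates.emissions import (
    log_emission_matrix,
    velocity_component_logpmf,
)

finite_v = st.floats(-60.0, 60.0, allow_nan=False)
sigmas = st.floats(1e-3, 50.0, allow_nan=False)


# ---------------------------------------------------------------- velocity

@pytest.mark.parametrize(
    "v, sigma, expected, tol",
    [
        # at v=0 the bell is 1 and both CDF tails are 1/2
        (0.0, 1.0, (0.5, 0.25, 0.25), 1e-12),
        # frozen high-precision evaluation of the PMF formulas
        (1.0, 1.0, (0.37754, 0.52371, 0.09875), 1e-4),
        # limit of a large positive velocity
        (50.0, 1.0, (0.0, 1.0, 0.0), 1e-12),
    ],
)
def test_velocity_pmf_reference_values(v, sigma, expected, tol):
    np.testing.assert_allclose(velocity_component_pmf(v, sigma), expected, atol=tol)


@given(v=finite_v, sigma=sigmas)
def test_velocity_pmf_normalisation(v, sigma):
    assert abs(velocity_component_pmf(v, sigma).sum() - 1.0) < 1e-12


@given(v=finite_v, sigma=sigmas)
def test_velocity_pmf_sign_symmetry(v, sigma):
    quiet_p, pos_p, neg_p = velocity_component_pmf(v, sigma)
    quiet_m, pos_m, neg_m = velocity_component_pmf(-v, sigma)
    assert quiet_p == pytest.approx(quiet_m, abs=1e-14)
    assert pos_p == pytest.approx(neg_m, abs=1e-14)
    assert neg_p == pytest.approx(pos_m, abs=1e-14)


@given(v=st.floats(-6.0, 2.0), dv=st.floats(1e-6, 4.0))
def test_velocity_pos_mass_strictly_increasing(v, dv):
    # unit width, |v/sigma| <= 6: strict growth is resolvable in float64
    _, pos_lo, _ = velocity_component_pmf(v, 1.0)
    _, pos_hi, _ = velocity_component_pmf(v + dv, 1.0)
    assert pos_hi > pos_lo


@given(v=finite_v, sigma=sigmas, k=st.floats(1e-3, 1e3))
def test_velocity_pmf_scale_equivariance(v, sigma, k):
    np.testing.assert_allclose(
        velocity_component_pmf(v, sigma), velocity_component_pmf(k * v, k * sigma),
        rtol=1e-9, atol=1e-12,
    )


@given(v=finite_v, sigma=sigmas)
def test_velocity_logpmf_consistent_with_pmf(v, sigma):
    np.testing.assert_allclose(
        np.exp(velocity_component_logpmf(v, sigma)), velocity_component_pmf(v, sigma),
        rtol=1e-9, atol=1e-300,
    )


def test_velocity_logpmf_stable_in_extreme_tails():
    out = velocity_component_logpmf(500.0, 1.0)
    assert np.all(np.isfinite(out[:2]))  # quiet and pos
    assert out[2] < -1e4                 # neg: astronomically unlikely, not -inf/nan


@pytest.mark.parametrize("bad_sigma", [0.0, -1.0, np.nan, np.inf])
def test_nonpositive_sigma_rejected(bad_sigma):
    with pytest.raises(ParameterError):
        velocity_component_pmf(0.5, bad_sigma)


# ---------------------------------------------------------------- diameter

@pytest.mark.parametrize(
    "d, mu, sigma, min_d, expected, tol",
    [
        # at the dilation threshold both CDFs are at their midpoint
        (2.5, 2.5, 0.4, 0.0, (0.5, 0.25, 0.25), 1e-12),
        # frozen high-precision evaluation
        (9.0, 8.0, 1.0, 0.0, (0.5, 0.42067, 0.07933), 1e-4),
        # fully distended limit
        (1e6, 8.0, 1.0, 0.0, (0.5, 0.5, 0.0), 1e-12),
    ],
)
def test_diameter_pmf_reference_values(d, mu, sigma, min_d, expected, tol):
    params = ModelParams(mu_d=mu, sigma_d=sigma)
    np.testing.assert_allclose(
        diameter_component_pmf(d, params, min_d=min_d), expected, atol=tol
    )


@given(d=st.floats(0.0, 100.0), mu=st.floats(0.0, 10.0), sigma=sigmas,
       min_d=st.floats(0.0, 10.0))
def test_diameter_pmf_normalisation_and_constant_any(d, mu, sigma, min_d):
    any_, dis, occ = diameter_component_pmf(d, ModelParams(mu_d=mu, sigma_d=sigma),
                                            min_d=min_d)
    assert abs(any_ + dis + occ - 1.0) < 1e-12
    assert any_ == 0.5


@given(d=st.floats(0.0, 40.0), dd=st.floats(1e-6, 10.0))
def test_diameter_dis_increasing_occ_decreasing(d, dd):
    # wide threshold keeps (d - mu_d)/sigma_d inside the CDF's resolvable range
    params = ModelParams(mu_d=20.0, sigma_d=8.0)
    lo = diameter_component_pmf(d, params, min_d=0.0)
    hi = diameter_component_pmf(d + dd, params, min_d=0.0)
    assert hi[1] > lo[1]
    assert hi[2] < lo[2]


def test_unresolved_min_d_raises():
    with pytest.raises(ParameterError, match="min_d"):
        diameter_component_pmf(5.0, ModelParams())


# ---------------------------------------------------------------- joint weight

def test_emission_weight_worked_example():
    # occluded quiescence at (d=min_d, 0, 0): 0.5 * Phi(mu/sigma) * 0.5 * 0.5
    params = ModelParams(sigma_d=0.4, mu_d=2.5, sigma_ddot=0.4, sigma_pdot=3.0)
    w = emission_weight((4.0, 0.0, 0.0), MechanicalState.OQ, params, min_d=4.0)
    assert w == pytest.approx(0.125, abs=1e-6)


def test_emission_weight_sum_matches_component_enumeration(rng):
    """Summing the 12 joint weights equals the direct product-sum over triples."""
    params = ModelParams()
    for _ in range(20):
        o = (rng.uniform(3, 15), rng.normal(0, 1), rng.normal(0, 5))
        weights = [emission_weight(o, s, params, min_d=3.0) for s in STATES]
        fd = diameter_component_pmf(o[0], params, min_d=3.0)
        fdd = velocity_component_pmf(o[1], params.sigma_ddot)
        fdp = velocity_component_pmf(o[2], params.sigma_pdot)
        d_order, v_order = ("any", "dis", "occ"), ("quiet", "pos", "neg")
        direct = sum(
            fd[d_order.index(s.diameter_component.value)]
            * fdd[v_order.index(s.d_velocity_component.value)]
            * fdp[v_order.index(s.p_velocity_component.value)]
            for s in STATES
        )
        assert sum(weights) == pytest.approx(direct, rel=1e-12)
        assert all(0 < w <= 1 for w in weights)


def test_occluded_isometric_contraction_dominates_pressure_rise():
    """Occluded diameter, still wall, sharply rising pressure -> oimc wins."""
    params = ModelParams()
    weights = {s: emission_weight((4.0, 0.0, 50.0), s, params, min_d=4.0)
               for s in STATES}
    assert max(weights, key=weights.get) is MechanicalState.OIMC


def test_log_emission_matrix_matches_scalar_weights(rng):
    params = ModelParams()
    d = rng.uniform(3, 15, 7)
    dd = rng.normal(0, 1, 7)
    dp = rng.normal(0, 5, 7)
    logb = log_emission_matrix(d, dd, dp, params, min_d=3.0)
    assert logb.shape == (7, 12)
    for i in range(7):
        for s in STATES:
            expected = emission_weight((d[i], dd[i], dp[i]), s, params, min_d=3.0)
            assert logb[i, s.value] == pytest.approx(np.log(expected), rel=1e-10)


def test_emission_weight_rejects_bad_observations():
    params = ModelParams()
    with pytest.raises(ValueError):
        emission_weight((np.nan, 0.0, 0.0), MechanicalState.OQ, params, min_d=0.0)
    with pytest.raises(ValueError):
        emission_weight((-1.0, 0.0, 0.0), MechanicalState.OQ, params, min_d=0.0)


# ---------------------------------------------------------------- priors

def test_priors_constant_quiet_observations():
    params = ModelParams()
    obs = [(4.0, 0.0, 0.0)] * 10
    priors = estimate_component_priors(obs, params, min_d=4.0)
    for element in ("d_dot", "p_dot"):
        assert priors[element]["quiet"] == pytest.approx(0.5, abs=1e-12)
        assert priors[element]["pos"] == pytest.approx(0.25, abs=1e-12)
        assert priors[element]["neg"] == pytest.approx(0.25, abs=1e-12)


def test_priors_symmetric_sample_balances_pos_neg():
    params = ModelParams()
    obs = [(5.0, -1.3, -4.0), (5.0, 1.3, 4.0)]
    priors = estimate_component_priors(obs, params, min_d=4.0)
    for element in ("d_dot", "p_dot"):
        assert priors[element]["pos"] == pytest.approx(priors[element]["neg"], abs=1e-14)


def test_priors_balanced_occupancy_near_one_third(rng):
    """Velocity priors approach 1/3 when quiet/pos/neg evidence balances.

    Maximum quiet mass is 1/2 (at v = 0), so balance needs two thirds of the
    samples quiet and one sixth strongly positive/negative each.  The
    diameter element's 'any' prior is pinned at 1/2 by the constant PMF, so
    only dis/occ balance there.
    """
    params = ModelParams()
    n = 1200
    dd = np.concatenate([rng.normal(0, 0.02, 2 * n // 3),
                         rng.uniform(3, 6, n // 6), -rng.uniform(3, 6, n // 6)])
    dp = np.concatenate([rng.normal(0, 0.2, 2 * n // 3),
                         rng.uniform(20, 40, n // 6), -rng.uniform(20, 40, n // 6)])
    d = np.concatenate([np.full(n // 2, 4.0), np.full(n // 2, 14.0)])
    obs = np.column_stack([d, dd, dp])
    priors = estimate_component_priors(list(map(tuple, obs)), params, min_d=4.0)
    for element in ("d_dot", "p_dot"):
        for comp in ("quiet", "pos", "neg"):
            assert abs(priors[element][comp] - 1 / 3) < 0.1
    assert priors["d"]["any"] == pytest.approx(0.5, abs=1e-12)
    assert priors["d"]["dis"] == pytest.approx(0.25, abs=0.05)
    assert priors["d"]["occ"] == pytest.approx(0.25, abs=0.05)
    for element_priors in priors.values():
        assert sum(element_priors.values()) == pytest.approx(1.0, abs=1e-12)


def test_priors_require_at_least_two_observations():
    with pytest.raises(ValueError):
        estimate_component_priors([(4.0, 0.0, 0.0)], ModelParams(), min_d=4.0)
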