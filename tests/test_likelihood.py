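"""Kernel tests: rectangle probabilities and the pair likelihood."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import ndtr
from scipy.stats import multivariate_normal, norm

from twingem.datatypes import PairMoments
from twingem.exceptions import DataValidationError, LikelihoodError
from twingem.likelihood import (
    PairArrays,
    PairObservation,
    bvn_upper_rect,
    classify_pattern,
    dataset_minus2ll,
    loglik_terms,
    pair_loglik,
)
from twingem.simulate import simulate_dataset

from conftest import single_group_config


# ---------------------------------------------------------------------------
# rectangle probability


@pytest.mark.parametrize("rho", [-0.9, -0.5, 0.0, 0.3, 0.5, 0.9])
def test_bvn_orthant_closed_form(rho):
    """P(Z1>0, Z2>0) = 1/4 + arcsin(rho)/(2 pi) to 1e-10."""
    expected = 0.25 + math.asin(rho) / (2 * math.pi)
    assert bvn_upper_rect(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-10)


def test_bvn_independence_and_limits():
    assert bvn_upper_rect(1.0, 2.0, 0.0) == pytest.approx(
        ndtr(-1.0) * ndtr(-2.0), abs=1e-12
    )
    assert bvn_upper_rect(-np.inf, -np.inf, 0.7) == pytest.approx(1.0, abs=1e-12)
    assert bvn_upper_rect(-np.inf, 1.5, -0.4) == pytest.approx(
        ndtr(-1.5), abs=1e-10
    )
    assert bvn_upper_rect(np.inf, 0.0, 0.2) == 0.0


def test_bvn_degenerate_correlations():
    # comonotone / antithetic closed forms
    assert bvn_upper_rect(0.5, -1.0, 1.0) == pytest.approx(ndtr(-0.5), abs=1e-12)
    assert bvn_upper_rect(-1.0, 0.0, -1.0) == pytest.approx(
        ndtr(-0.0) - ndtr(-1.0), abs=1e-12
    )
    assert bvn_upper_rect(0.5, -0.2, -1.0) == pytest.approx(
        max(0.0, ndtr(0.2) - ndtr(0.5)), abs=1e-12
    )
    with pytest.raises(LikelihoodError):
        bvn_upper_rect(0.0, 0.0, 1.5)


def _quad_oracle(h, k, rho):
    """Independent adaptive-quadrature evaluation of the conditional form,
    piecewise so each segment converges to ~1e-13 absolute."""
    s = math.sqrt(1 - rho * rho)

    def f(z):
        return norm.pdf(z) * ndtr((rho * z - k) / s)

    cuts = [h] + [c for c in (-1.0, 0.0, 1.0, 3.0) if c > h] + [12.0]
    val = 0.0
    total_err = 0.0
    for a, b in zip(cuts, cuts[1:]):
        v, err = integrate.quad(f, a, b, epsabs=1e-13, limit=200)
        val += v
        total_err += err
    assert total_err < 5e-11
    return val


@pytest.mark.parametrize("h", [-2.0, 0.0, 2.0])
@pytest.mark.parametrize("k", [-2.0, 0.0, 2.0])
@pytest.mark.parametrize("rho", [-0.9, -0.5, 0.0, 0.5, 0.9])
def test_bvn_vs_adaptive_quadrature(h, k, rho):
    assert bvn_upper_rect(h, k, rho) == pytest.approx(
        _quad_oracle(h, k, rho), abs=1e-10
    )


def test_bvn_vs_scipy_genz():
    rng = np.random.default_rng(7)
    for _ in range(30):
        h, k = rng.uniform(-3, 3, size=2)
        rho = rng.uniform(-0.95, 0.95)
        ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([-h, -k])
        assert bvn_upper_rect(h, k, rho) == pytest.approx(ref, abs=5e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    h=st.floats(-5, 5),
    k=st.floats(-5, 5),
    rho=st.floats(-0.99, 0.99),
)
def test_bvn_bounds_and_monotonicity(h, k, rho):
    p = bvn_upper_rect(h, k, rho)
    assert 0.0 <= p <= min(ndtr(-h), ndtr(-k)) + 1e-12
    assert bvn_upper_rect(h + 0.5, k, rho) <= p + 1e-12


# ---------------------------------------------------------------------------
# observation patterns


@pytest.mark.parametrize(
    "y1,y2,c1,c2,expected",
    [
        (540.0, 541.0, False, False, "OO"),
        (540.0, 550.0, False, True, "OC"),
        (550.0, 540.0, True, False, "CO"),
        (550.0, 550.0, True, True, "CC"),
        (540.0, None, False, False, "O_"),
        (550.0, None, True, False, "C_"),
        (None, 540.0, False, False, "_O"),
        (None, 550.0, False, True, "_C"),
    ],
)
def test_pattern_classification(y1, y2, c1, c2, expected):
    assert classify_pattern(y1, y2, c1, c2) == expected
    assert PairObservation(y1, y2, c1, c2).pattern == expected


def test_pattern_rejects_inconsistencies():
    with pytest.raises(DataValidationError):
        classify_pattern(None, None, False, False)
    with pytest.raises(DataValidationError):
        classify_pattern(None, 540.0, True, False)


# ---------------------------------------------------------------------------
# pair likelihood


def test_oo_independence_factorizes():
    mom = PairMoments(535.0, 536.0, 80.0, 70.0, 0.0)
    obs = PairObservation(530.0, 545.0)
    expected = norm.logpdf(530.0, 535.0, math.sqrt(80.0)) + norm.logpdf(
        545.0, 536.0, math.sqrt(70.0)
    )
    assert pair_loglik(obs, mom, 550.0) == pytest.approx(expected, abs=1e-10)


def test_oo_uncensored_limit_matches_bvn_density():
    mom = PairMoments(535.0, 536.0, 81.0, 81.0, 40.0)
    obs = PairObservation(548.0, 549.0)
    ref = multivariate_normal(
        mean=[535.0, 536.0], cov=[[81.0, 40.0], [40.0, 81.0]]
    ).logpdf([548.0, 549.0])
    assert pair_loglik(obs, mom, np.inf) == pytest.approx(ref, abs=1e-10)
    # for an interior OO pair the finite threshold changes nothing
    assert pair_loglik(obs, mom, 550.0) == pytest.approx(ref, abs=1e-10)


def test_cc_pattern_matches_monte_carlo():
    """Both-censored probability against a simulation oracle."""
    mom = PairMoments(548.0, 548.0, 81.0, 81.0, 40.5)
    obs = PairObservation(550.0, 550.0, True, True)
    ll = pair_loglik(obs, mom, 550.0)
    rng = np.random.default_rng(2024)
    n = 2_000_000
    z1 = rng.standard_normal(n)
    z2 = 0.5 * z1 + math.sqrt(1 - 0.25) * rng.standard_normal(n)
    y1 = 548.0 + 9.0 * z1
    y2 = 548.0 + 9.0 * z2
    p_hat = np.mean((y1 >= 550.0) & (y2 >= 550.0))
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    assert math.exp(ll) == pytest.approx(p_hat, abs=3 * se)


def test_singleton_patterns():
    mom = PairMoments(540.0, 540.0, 64.0, 64.0, 30.0)
    assert pair_loglik(PairObservation(545.0, None), mom, 550.0) == pytest.approx(
        norm.logpdf(545.0, 540.0, 8.0), abs=1e-10
    )
    assert pair_loglik(
        PairObservation(550.0, None, True, False), mom, 550.0
    ) == pytest.approx(norm.logsf(550.0, 540.0, 8.0), abs=1e-10)


def test_swap_symmetry():
    mom = PairMoments(535.0, 538.0, 81.0, 64.0, 30.0)
    swapped = PairMoments(538.0, 535.0, 64.0, 81.0, 30.0)
    for obs, obs_sw in [
        (PairObservation(530.0, 544.0), PairObservation(544.0, 530.0)),
        (
            PairObservation(530.0, 550.0, False, True),
            PairObservation(550.0, 530.0, True, False),
        ),
    ]:
        assert pair_loglik(obs, mom, 550.0) == pytest.approx(
            pair_loglik(obs_sw, swapped, 550.0), abs=1e-10
        )


def test_continuity_in_mean_across_threshold():
    """-2LL is smooth in mu as probability mass crosses the ceiling."""
    obs = [
        PairObservation(549.0, 550.0, False, True),
        PairObservation(550.0, 550.0, True, True),
        PairObservation(544.0, 547.0),
    ]
    mus = np.linspace(540.0, 556.0, 161)
    vals = []
    for mu in mus:
        mom = PairMoments(mu, mu, 81.0, 81.0, 40.0)
        vals.append(sum(pair_loglik(o, mom, 550.0) for o in obs))
    steps = np.abs(np.diff(vals))
    assert np.max(steps) < 0.2  # no jumps at 0.1-unit mean steps


def test_invalid_moments_and_data_rejected():
    mom_bad = PairMoments(535.0, 535.0, 81.0, 81.0, 80.999999999)
    obs = PairObservation(540.0, 541.0)
    # exactly singular moments are rejected
    with pytest.raises(LikelihoodError):
        pair_loglik(obs, PairMoments(0.0, 0.0, 1.0, 1.0, 1.0), 550.0)
    del mom_bad
    with pytest.raises(DataValidationError):
        pair_loglik(
            PairObservation(549.0, 540.0, True, False),
            PairMoments(535.0, 535.0, 81.0, 81.0, 40.0),
            550.0,
        )


# ---------------------------------------------------------------------------
# dataset-level evaluation


def _const_moments(mom):
    return lambda rec: mom


def test_dataset_minus2ll_empty_and_additive(small_censored_cohort):
    _, df = small_censored_cohort
    mom = PairMoments(535.0, 535.0, 81.0, 81.0, 40.0)
    assert dataset_minus2ll(df.iloc[0:0], _const_moments(mom)) == 0.0
    one = dataset_minus2ll(df, _const_moments(mom))
    import pandas as pd

    two = dataset_minus2ll(
        pd.concat([df, df], ignore_index=True), _const_moments(mom)
    )
    assert two == pytest.approx(2 * one, rel=1e-12)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert dataset_minus2ll(shuffled, _const_moments(mom)) == pytest.approx(
        one, rel=1e-12
    )


def test_dataset_minus2ll_uncensored_matches_direct_fiml():
    """Textbook bivariate-normal FIML computed independently with scipy."""
    cfg = single_group_config(n_mz=60, n_dz=60)
    df = simulate_dataset(cfg)  # latent: no censoring applied
    mom = PairMoments(535.0, 535.0, 81.0, 81.0, 52.0)
    ours = dataset_minus2ll(df, _const_moments(mom), threshold=np.inf)
    mvn = multivariate_normal(
        mean=[535.0, 535.0], cov=[[81.0, 52.0], [52.0, 81.0]]
    )
    ref = -2 * mvn.logpdf(df[["ea1", "ea2"]].to_numpy()).sum()
    assert ours == pytest.approx(ref, rel=1e-12)


def test_dataset_rejects_fully_missing_pair(small_censored_cohort):
    _, df = small_censored_cohort
    bad = df.copy()
    bad.loc[0, ["ea1", "ea2"]] = np.nan
    bad.loc[0, ["cens1", "cens2"]] = False
    with pytest.raises(DataValidationError):
        PairArrays.from_frame(bad)


def test_loglik_terms_rejects_non_pd():
    pa = PairArrays(
        np.array([540.0]), np.array([541.0]),
        np.array([False]), np.array([False]), 550.0,
    )
    with pytest.raises(LikelihoodError):
        loglik_terms(
            pa, np.array([535.0]), np.array([535.0]),
            np.array([81.0]), np.array([81.0]), np.array([82.0]),
        )
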