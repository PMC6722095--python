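"""Twin-model tests: implied moments, FIML fits, LRTs, profile CIs."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twingem.datatypes import ACEParams, ModelSpec
from twingem.exceptions import DataValidationError, NotNestedError
from twingem.model import (
    FIMLProblem,
    fit,
    implied_cov,
    lrt,
    profile_ci,
    saturated_twin_correlation,
    standardize,
)
from twingem.simulate import apply_censoring, simulate_dataset

from conftest import single_group_config


def test_implied_cov_reference_values():
    ace = ACEParams(65.9, 2.7, 17.9)
    mz = implied_cov(ace, "MZ")
    assert mz[0, 0] == pytest.approx(86.5)
    assert mz[0, 1] == pytest.approx(68.6)
    dz = implied_cov(ACEParams(40.0, 0.0, 10.0), "DZ")
    assert dz[0, 1] == pytest.approx(20.0)
    indep = implied_cov(ACEParams(0.0, 0.0, 5.0), "MZ")
    assert indep[0, 1] == 0.0 and indep[0, 0] == 5.0


def test_standardize():
    props = standardize(ACEParams(65.9, 2.7, 17.9))
    assert props["h2"] == pytest.approx(0.76, abs=0.005)
    assert standardize(ACEParams(0.0, 0.0, 4.0)) == {
        "h2": 0.0, "c2": 0.0, "e2": 1.0
    }


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    a2=st.floats(0.0, 100.0),
    c2=st.floats(0.0, 50.0),
    e2=st.floats(0.1, 50.0),
)
def test_standardize_sums_to_one(a2, c2, e2):
    props = standardize(ACEParams(a2, c2, e2))
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)


def test_fit_recovers_single_group(small_censored_cohort):
    cfg, df = small_censored_cohort
    res = fit(df, ModelSpec(), n_starts=2)
    assert res.converged
    true_ace = cfg.ace_variances[0]
    assert res.mean() == pytest.approx(535.0, abs=0.8)
    assert res.ace().a2 == pytest.approx(true_ace.a2, rel=0.30)
    assert res.ace().total == pytest.approx(true_ace.total, rel=0.10)


def test_fit_c_boundary_when_generated_without_c():
    cfg = single_group_config(ace=ACEParams(55.0, 0.0, 20.0), n_mz=1200, n_dz=1200)
    df = simulate_dataset(cfg)  # uncensored
    res = fit(df, ModelSpec(censoring=False), n_starts=2)
    assert res.estimates["c2"] < 4.0  # at or near the 0 boundary


def test_nesting_monotonicity_and_lrt(small_censored_cohort):
    _, df = small_censored_cohort
    parent = fit(df, ModelSpec(), n_starts=2)
    nested = fit(df, ModelSpec(include_c=False), n_starts=2)
    assert nested.minus2ll >= parent.minus2ll - 1e-3
    t = lrt(parent, nested)
    assert t.delta_df == 1
    assert 0.0 <= t.p_value <= 1.0
    with pytest.raises(NotNestedError):
        lrt(nested, parent)


def test_lrt_identical_fits_gives_p_one(small_censored_cohort):
    _, df = small_censored_cohort
    parent = fit(df, ModelSpec(), n_starts=1)
    nested = dataclasses.replace(
        parent,
        spec=ModelSpec(include_c=False),
        n_free_params=parent.n_free_params - 1,
    )
    t = lrt(parent, nested)
    assert t.delta_minus2ll == 0.0
    assert t.p_value == 1.0


def test_non_nested_specs_rejected(small_censored_cohort):
    _, df = small_censored_cohort
    a = fit(df, ModelSpec(include_c=False), n_starts=1)
    b = fit(
        df,
        ModelSpec(stratify_means_by_ses=True, include_c=False),
        n_starts=1,
    )
    bad = dataclasses.replace(
        b, spec=ModelSpec(include_c=True), n_free_params=a.n_free_params - 1
    )
    with pytest.raises(NotNestedError):
        lrt(a, bad)


def test_ace_requires_both_zygosities():
    cfg = single_group_config(n_mz=150, n_dz=0)
    df = apply_censoring(simulate_dataset(cfg))
    with pytest.raises(DataValidationError):
        fit(df, ModelSpec())
    # AE model is identified from one zygosity
    res = fit(df, ModelSpec(include_c=False), n_starts=1)
    assert np.isfinite(res.minus2ll)


def test_empty_ses_cell_rejected(small_censored_cohort):
    _, df = small_censored_cohort  # single stratum (ses == 1)
    spec = ModelSpec(stratify_means_by_ses=True)
    res = fit(df, spec, n_starts=1)  # its own groups: fine
    assert res.groups == ("lowest",)
    with pytest.raises(DataValidationError):
        fit(df.iloc[0:0], spec)


def test_minus2ll_swap_invariance(small_censored_cohort):
    """Relabelling twin 1/twin 2 leaves the objective unchanged."""
    _, df = small_censored_cohort
    swapped = df.rename(
        columns={
            "ea1": "ea2", "ea2": "ea1", "cens1": "cens2", "cens2": "cens1",
            "sex1": "sex2", "sex2": "sex1", "pgs1": "pgs2", "pgs2": "pgs1",
        }
    )
    spec = ModelSpec()
    p1 = FIMLProblem(df, spec)
    p2 = FIMLProblem(swapped, spec)
    theta = p1.start()
    assert p1.minus2ll(theta) == pytest.approx(p2.minus2ll(theta), rel=1e-12)


def test_saturated_correlation_uncensored_matches_closed_form():
    """Against the exchangeable-ML closed form on uncensored pairs."""
    cfg = single_group_config(n_mz=1500, n_dz=0, ace=ACEParams(48.0, 0.0, 33.0))
    df = simulate_dataset(cfg)
    est = saturated_twin_correlation(df, "MZ", censoring=False, include_sex=False)
    y1 = df["ea1"].to_numpy()
    y2 = df["ea2"].to_numpy()
    mu = 0.5 * (y1.mean() + y2.mean())
    s1 = np.sum((y1 - mu) ** 2) + np.sum((y2 - mu) ** 2)
    s12 = np.sum((y1 - mu) * (y2 - mu))
    assert est.rho == pytest.approx(2 * s12 / s1, abs=1e-4)


def test_saturated_correlation_censored_recovery_and_null():
    cfg = single_group_config(
        n_mz=2000, n_dz=0, ace=ACEParams(63.99, 0.0, 17.01)
    )  # rMZ = 0.79 on the 535/9 scale
    df = apply_censoring(simulate_dataset(cfg))
    est = saturated_twin_correlation(df, "MZ")
    assert est.rho == pytest.approx(0.79, abs=0.03)
    cfg0 = single_group_config(n_mz=800, n_dz=0, ace=ACEParams(0.0, 0.0, 81.0))
    df0 = apply_censoring(simulate_dataset(cfg0))
    est0 = saturated_twin_correlation(df0, "MZ")
    assert est0.rho == pytest.approx(0.0, abs=0.08)
    with pytest.raises(DataValidationError):
        saturated_twin_correlation(df0.iloc[:1], "MZ")


def test_profile_ci_contains_estimate_and_matches_wald():
    """Profile bounds vs a Wald oracle from the numerical Hessian."""
    cfg = single_group_config(n_mz=2500, n_dz=2500)
    df = apply_censoring(simulate_dataset(cfg))
    spec = ModelSpec()
    res = fit(df, spec, n_starts=2)
    lo, hi = profile_ci(df, spec, res, "mu", level=0.95)
    est = res.estimates["mu"]
    assert lo < est < hi
    # Wald oracle: marginal SE from the full numerical Hessian of -2LL
    prob = FIMLProblem(df, spec)
    theta = prob.theta_from_estimates(res.estimates)
    i_mu = prob.free_names.index("mu")
    k = len(theta)
    h = 0.05
    hess = np.empty((k, k))
    f0 = prob.minus2ll(theta)
    for i in range(k):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        hess[i, i] = (prob.minus2ll(tp) - 2 * f0 + prob.minus2ll(tm)) / (h * h)
        for j in range(i + 1, k):
            tpp = theta.copy(); tpp[i] += h; tpp[j] += h
            tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
            tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
            tmp_ = theta.copy(); tmp_[i] -= h; tmp_[j] += h
            hess[i, j] = hess[j, i] = (
                prob.minus2ll(tpp) - prob.minus2ll(tpm)
                - prob.minus2ll(tmp_) + prob.minus2ll(tmm)
            ) / (4 * h * h)
    se = np.sqrt(2.0 * np.linalg.inv(hess)[i_mu, i_mu])
    assert lo == pytest.approx(est - 1.96 * se, abs=0.25 * se)
    assert hi == pytest.approx(est + 1.96 * se, abs=0.25 * se)


def test_profile_ci_variance_boundary():
    cfg = single_group_config(ace=ACEParams(55.0, 0.0, 20.0), n_mz=700, n_dz=700)
    df = apply_censoring(simulate_dataset(cfg))
    spec = ModelSpec()
    res = fit(df, spec, n_starts=2)
    lo, hi = profile_ci(df, spec, res, "c2", level=0.95)
    assert lo == 0.0
    assert hi > res.estimates["c2"]
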