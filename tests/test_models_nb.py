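"""Count-family (NB mixed model) likelihood and fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from pairpower import (
    DesignSpec,
    NBParams,
    SampleTable,
    ValidationError,
    build_design,
    fit_nb_glmm,
    nb_glmm_loglik,
)
from conftest import simulate_nb


def grid_integral_loglik(y, table, params, span=10.0, n_grid=10001):
    """Trapezoid-rule oracle: integrate the random effect per subject
    on a fine fixed grid."""
    t = table.treatment_indicator()
    eta = table.offsets() + params.mu + params.delta * t
    theta = params.theta
    sd = math.sqrt(params.sigma2_subj)
    bs = np.linspace(-span * sd, span * sd, n_grid)
    total = 0.0
    for subject, idx in table.data.groupby("subject_id", sort=False).indices.items():
        lg = stats.norm.logpdf(bs, 0.0, sd)
        for i in idx:
            m = np.exp(eta[i] + bs)
            lg = lg + stats.nbinom.logpmf(y[i], theta, theta / (theta + m))
        total += logsumexp(lg) + math.log(bs[1] - bs[0])
    return total


@pytest.mark.parametrize(
    "params",
    [
        NBParams(mu=math.log(100), delta=0.22, sigma2_subj=0.5, scale=1.15),
        NBParams(mu=math.log(20), delta=-0.7, sigma2_subj=1.5, scale=0.8),
        NBParams(mu=math.log(500), delta=0.0, sigma2_subj=0.1, scale=1.5),
    ],
)
def test_quadrature_matches_grid_integration(tiny_paired_table, params):
    """Adaptive Gauss-Hermite equals fine-grid integration to <= 1e-6."""
    y = np.array([130.0, 85.0, 40.0, 210.0])
    ll = nb_glmm_loglik(y, tiny_paired_table, params)
    oracle = grid_integral_loglik(y, tiny_paired_table, params)
    assert ll == pytest.approx(oracle, abs=1e-6)


def test_degenerate_random_effect_is_plain_nb(tiny_paired_table):
    params = NBParams(mu=math.log(50), delta=0.3, sigma2_subj=0.0, scale=1.15)
    y = np.array([60.0, 45.0, 80.0, 30.0])
    t = tiny_paired_table.treatment_indicator()
    m = np.exp(params.mu + params.delta * t)
    expected = stats.nbinom.logpmf(y, params.theta, params.theta / (params.theta + m)).sum()
    assert nb_glmm_loglik(y, tiny_paired_table, params) == pytest.approx(expected, abs=1e-10)


def test_large_theta_approaches_poisson_lognormal(tiny_paired_table):
    """As the NB dispersion vanishes (theta large) the model tends to
    the Poisson-lognormal mixture, computed here by grid integration."""
    y = np.array([130.0, 85.0, 40.0, 210.0])
    s2s = 0.4
    mu, delta = math.log(100), 0.22
    big_theta = 1.0e7
    params = NBParams(mu=mu, delta=delta, sigma2_subj=s2s, scale=math.sqrt(1.0 / big_theta))
    ll = nb_glmm_loglik(y, tiny_paired_table, params)
    # Poisson-lognormal oracle
    t = tiny_paired_table.treatment_indicator()
    eta = mu + delta * t
    sd = math.sqrt(s2s)
    bs = np.linspace(-10 * sd, 10 * sd, 20001)
    total = 0.0
    for subject, idx in tiny_paired_table.data.groupby("subject_id", sort=False).indices.items():
        lg = stats.norm.logpdf(bs, 0.0, sd)
        for i in idx:
            lg = lg + stats.poisson.logpmf(y[i], np.exp(eta[i] + bs))
        total += logsumexp(lg) + math.log(bs[1] - bs[0])
    assert ll == pytest.approx(total, abs=1e-4)


def test_counts_validated(tiny_paired_table):
    params = NBParams(mu=0.0, delta=0.0, sigma2_subj=0.1, scale=1.0)
    with pytest.raises(ValidationError):
        nb_glmm_loglik(np.array([1.0, -2.0, 3.0, 4.0]), tiny_paired_table, params)
    with pytest.raises(ValidationError):
        nb_glmm_loglik(np.array([1.5, 2.0, 3.0, 4.0]), tiny_paired_table, params)


def test_nb_glm_matches_statsmodels():
    """The in-package NB regression (no random effect) agrees with
    statsmodels' independent ML implementation."""
    sm = pytest.importorskip("statsmodels.api")
    table = build_design(DesignSpec(60, 0.0))
    rng = np.random.default_rng(3)
    y = simulate_nb(table, math.log(80), 0.4, 0.0, 1.1, rng)
    res = fit_nb_glmm(y, table, include_random=False)
    X = np.column_stack([np.ones(60), table.treatment_indicator()])
    ref = sm.NegativeBinomial(y, X).fit(disp=0)
    assert res.estimates["mu"] == pytest.approx(ref.params[0], abs=1e-5)
    assert res.estimates["delta"] == pytest.approx(ref.params[1], abs=1e-5)
    # statsmodels reports alpha = k = 1/theta
    assert res.estimates["theta"] == pytest.approx(1.0 / ref.params[2], rel=1e-4)


def test_nb_glm_with_covariates_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    table = build_design(DesignSpec(50, 0.0))
    rng = np.random.default_rng(7)
    data = table.data.copy()
    data["age"] = rng.normal(64, 10, 50)
    data["sex"] = rng.choice(["F", "M"], 50)
    table = SampleTable(data)
    y = simulate_nb(table, math.log(60), 0.3, 0.0, 1.0, rng)
    res = fit_nb_glmm(y, table, include_random=False, covariates=["age", "sex"])
    sex_ref = data["sex"].iloc[0]  # first-observed level is the reference
    X = np.column_stack([
        np.ones(50), table.treatment_indicator(),
        data["age"], (data["sex"] != sex_ref).astype(float),
    ])
    ref = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
    assert np.allclose(
        [res.estimates["mu"], res.estimates["delta"]], ref.params[:2], atol=1e-4
    )


def test_variance_floors_and_delta_matches_glm():
    """On data generated without subject effects the GLMM variance
    component floors at ~0 and the treatment estimate coincides with
    the plain NB regression."""
    table = build_design(DesignSpec(100, 1.0))
    rng = np.random.default_rng(0)
    y = simulate_nb(table, math.log(100), 0.22, 0.0, 1.15, rng)
    r1 = fit_nb_glmm(y, table, include_random=True, precise=True)
    r0 = fit_nb_glmm(y, table, include_random=False)
    assert r1.estimates["sigma2_subj"] <= 1e-6
    assert abs(r1.delta - r0.delta) <= 1e-4


def test_glmm_type_i_error_calibrated():
    """Null rejection rate of the GLMM Wald t test is near the nominal
    5% level (binomial Monte-Carlo tolerance)."""
    from pairpower import PowerQuery
    from pairpower.simulate import simulate_test_power

    query = PowerQuery(
        DesignSpec(30, 1.0), "count", NBParams(0.0, 0.0, 0.5, 1.15), alpha=0.05
    )
    n_sims = 300
    rate, se = simulate_test_power(query, n_sims, seed=5)
    assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_sims)


def test_rank_deficient_design_rejected():
    table = build_design(DesignSpec(10, 0.0))
    data = table.data.copy()
    data["dup"] = table.treatment_indicator()  # collinear with TRT
    table = SampleTable(data)
    with pytest.raises(ValidationError):
        fit_nb_glmm(np.ones(10), table, include_random=False, covariates=["dup"])
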