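"""Continuous-family likelihood and fitting against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairpower import (
    DesignSpec,
    LMMParams,
    SampleTable,
    ValidationError,
    build_design,
    fit_lmm,
    lmm_loglik,
)
from conftest import simulate_lmm


def dense_mvn_loglik(y, table, params):
    """Brute-force oracle: full dense covariance, scipy MVN density."""
    n = table.n_samples
    codes = table.data["subject_id"].astype("category").cat.codes.to_numpy()
    V = params.sigma2_subj * (codes[:, None] == codes[None, :]).astype(float)
    V += params.sigma2_err * np.eye(n)
    mean = params.mu + params.delta * table.treatment_indicator()
    return stats.multivariate_normal.logpdf(y, mean=mean, cov=V)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("q", [0.0, 0.4, 1.0])
def test_loglik_matches_dense_oracle(seed, q):
    """Blockwise marginal likelihood equals the dense MVN density."""
    rng = np.random.default_rng(seed)
    table = build_design(DesignSpec(12, q))
    params = LMMParams(
        mu=rng.normal(), delta=rng.normal(), sigma2_subj=rng.uniform(0, 2),
        sigma2_err=rng.uniform(0.2, 2),
    )
    y = rng.normal(size=12)
    assert lmm_loglik(y, table, params) == pytest.approx(
        dense_mvn_loglik(y, table, params), abs=1e-8
    )


def test_loglik_single_subject_at_mean():
    """A lone sample at its mean contributes -0.5 log(2 pi v)."""
    table = SampleTable(
        pd.DataFrame({"subject_id": ["A", "B"], "condition": ["tumor", "normal"],
                      "offset": [0.0, 0.0]})
    )
    params = LMMParams(mu=2.0, delta=0.5, sigma2_subj=0.3, sigma2_err=0.7)
    y = np.array([2.5, 2.0])  # both exactly at their means
    v = params.sigma2_subj + params.sigma2_err
    assert lmm_loglik(y, table, params) == pytest.approx(
        2 * (-0.5 * math.log(2 * math.pi * v)), abs=1e-12
    )


def test_loglik_zero_subject_variance_factorizes(tiny_paired_table):
    params = LMMParams(mu=1.0, delta=0.3, sigma2_subj=0.0, sigma2_err=0.9)
    y = np.array([1.7, 0.6, 1.1, 1.4])
    mean = params.mu + params.delta * tiny_paired_table.treatment_indicator()
    expected = stats.norm.logpdf(y, mean, math.sqrt(params.sigma2_err)).sum()
    assert lmm_loglik(y, tiny_paired_table, params) == pytest.approx(expected, abs=1e-12)


def test_loglik_rejects_nonfinite(paired_table):
    y = np.full(20, np.nan)
    with pytest.raises(ValidationError):
        lmm_loglik(y, paired_table, LMMParams(0, 0, 1, 1))


def test_fully_paired_delta_is_mean_difference(paired_table):
    rng = np.random.default_rng(4)
    y = simulate_lmm(paired_table, 5.0, 0.4, 1.0, 1.7, rng)
    res = fit_lmm(y, paired_table)
    pairs = paired_table.pair_indices()
    d = (y[pairs[:, 0]] - y[pairs[:, 1]]).mean()
    assert res.delta == pytest.approx(d, abs=1e-8)
    assert res.converged
    assert res.df == 20 - 2 - 10


def test_ml_beats_grid_search(paired_table):
    """The optimizer's variance components maximize the likelihood
    against a brute-force grid around the optimum."""
    rng = np.random.default_rng(9)
    y = simulate_lmm(paired_table, 0.0, 0.5, 0.8, 1.0, rng)
    res = fit_lmm(y, paired_table)
    est = res.estimates
    best = res.log_likelihood
    for s2s in np.linspace(max(est["sigma2_subj"] - 0.5, 1e-3), est["sigma2_subj"] + 0.5, 15):
        for s2e in np.linspace(max(est["sigma2_err"] - 0.5, 1e-3), est["sigma2_err"] + 0.5, 15):
            ll = lmm_loglik(
                y, paired_table,
                LMMParams(est["mu"], est["delta"], s2s, s2e),
            )
            assert ll <= best + 1e-6


def test_unpaired_analysis_is_classical_t():
    """Dropping the random effect reproduces the pooled two-sample t
    statistic and p-value exactly."""
    table = build_design(DesignSpec(30, 0.0))
    rng = np.random.default_rng(11)
    y = simulate_lmm(table, 1.0, 0.6, 0.5, 1.0, rng)
    res = fit_lmm(y, table, include_random=False)
    t = table.treatment_indicator()
    t_ref, p_ref = stats.ttest_ind(y[t == 1], y[t == 0], equal_var=True)
    assert res.statistic == pytest.approx(t_ref, abs=1e-12)
    assert res.p_value == pytest.approx(p_ref, abs=1e-12)
    assert res.df == 28
    # estimates equal ordinary least squares (difference of group means)
    assert res.delta == pytest.approx(y[t == 1].mean() - y[t == 0].mean(), abs=1e-12)


def test_include_random_false_on_paired_data(paired_table):
    """The unpaired analysis of paired data is the plain two-group fit."""
    rng = np.random.default_rng(12)
    y = simulate_lmm(paired_table, 0.0, 0.4, 2.0, 0.5, rng)
    res = fit_lmm(y, paired_table, include_random=False)
    t = paired_table.treatment_indicator()
    assert res.delta == pytest.approx(y[t == 1].mean() - y[t == 0].mean(), abs=1e-12)


def test_minimum_subjects_enforced():
    """Designs too small to estimate the model are rejected outright
    (the analytic power surface marks these cells missing instead)."""
    table = build_design(DesignSpec(4, 1.0))  # 2 subjects
    rng = np.random.default_rng(0)
    y = simulate_lmm(table, 0.0, 0.1, 0.5, 1.0, rng)
    with pytest.raises(ValidationError):
        fit_lmm(y, table)


def test_one_condition_absent_rejected():
    table = SampleTable(
        pd.DataFrame({"subject_id": ["A", "B", "C"], "condition": ["tumor"] * 3,
                      "offset": [0.0] * 3})
    )
    with pytest.raises(ValidationError):
        fit_lmm(np.zeros(3), table)
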