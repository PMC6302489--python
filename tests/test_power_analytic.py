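"""Analytic (exemplary-data noncentral-F) power approximation."""

import math

import numpy as np
import pytest
from scipy import stats

from pairpower import (
    DesignSpec,
    LMMParams,
    NBParams,
    PowerQuery,
    ValidationError,
    build_design,
    gls_var_delta,
    log_fold_change,
    power_exemplary,
    power_grid,
)


def test_log_fold_change_values():
    """The study's target fold changes map to the printed log effects."""
    assert round(log_fold_change(1.25), 2) == 0.22
    assert round(log_fold_change(1.5), 2) == 0.41
    with pytest.raises(ValidationError):
        log_fold_change(-1.0)


class TestGlsVarDelta:
    def test_fully_unpaired_closed_form(self):
        table = build_design(DesignSpec(40, 0.0))
        params = LMMParams(0, 0.4, 0.7, 1.3)
        v = gls_var_delta(table, "continuous", params)
        assert v == pytest.approx(2 * (0.7 + 1.3) / 20, abs=1e-12)

    def test_fully_paired_closed_form(self):
        table = build_design(DesignSpec(40, 1.0))
        params = LMMParams(0, 0.4, 5.0, 1.3)
        # the subject variance cancels in within-pair differences
        assert gls_var_delta(table, "continuous", params) == pytest.approx(
            2 * 1.3 / 20, abs=1e-12
        )

    @pytest.mark.parametrize("family", ["continuous", "count"])
    def test_mixed_design_matches_dense_gls(self, family):
        """Blockwise accumulation equals the brute-force dense
        (X' V^-1 X)^-1 with the full covariance matrix."""
        table = build_design(DesignSpec(20, 0.5))  # 5 paired + 5 per arm
        t = table.treatment_indicator()
        X = np.column_stack([np.ones(20), t])
        codes = table.data["subject_id"].astype("category").cat.codes.to_numpy()
        same = (codes[:, None] == codes[None, :]).astype(float)
        if family == "continuous":
            params = LMMParams(0, 0.4, 1.0, 1.0)
            V = 1.0 * same + 1.0 * np.eye(20)
        else:
            params = NBParams(0, 0.22, 1.0, 1.15)
            m = 100.0 * np.exp(params.delta * t)
            V = params.sigma2_subj * same + np.diag(1.0 / m + params.k)
        v = gls_var_delta(table, family, params, baseline_mean_count=100.0)
        dense = np.linalg.inv(X.T @ np.linalg.inv(V) @ X)[1, 1]
        assert v == pytest.approx(dense, rel=1e-10)

    def test_one_condition_absent_rejected(self):
        import pandas as pd
        from pairpower import SampleTable

        table = SampleTable(
            pd.DataFrame({"subject_id": ["A", "B"], "condition": ["tumor"] * 2,
                          "offset": [0.0, 0.0]})
        )
        with pytest.raises(ValidationError):
            gls_var_delta(table, "continuous", LMMParams(0, 0.4, 1, 1))


class TestPowerExemplary:
    def test_size_equals_level(self):
        q = PowerQuery(DesignSpec(40, 0.5), "continuous", LMMParams(0, 0.0, 1, 1))
        assert power_exemplary(q) == pytest.approx(0.05, abs=1e-12)

    def test_unpaired_equals_two_sample_t_power(self):
        """Fully unpaired analytic power equals the classical
        noncentral-t two-sample power to 1e-10."""
        s2s, s2e, d, n = 1.0, 1.73, 0.41, 100
        q = PowerQuery(DesignSpec(n, 0.0), "continuous", LMMParams(0, d, s2s, s2e))
        se = math.sqrt(2 * (s2s + s2e) / (n / 2))
        df = n - 2
        tcrit = stats.t.ppf(0.975, df)
        nc = d / se
        oracle = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        assert abs(power_exemplary(q) - oracle) <= 1e-10

    def test_paired_equals_paired_t_power(self):
        """Fully paired analytic power equals the noncentral-t power
        with Var(delta-hat) = 2 sigma^2 / P under the df rule."""
        s2s, s2e, d, n = 1.0, 1.73, 0.41, 100
        p = n // 2
        q = PowerQuery(DesignSpec(n, 1.0), "continuous", LMMParams(0, d, s2s, s2e))
        se = math.sqrt(2 * s2e / p)
        df = n - 2 - p
        tcrit = stats.t.ppf(0.975, df)
        nc = d / se
        oracle = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        assert abs(power_exemplary(q) - oracle) <= 1e-10

    def test_missing_when_df_exhausted(self):
        q = PowerQuery(DesignSpec(4, 1.0), "continuous", LMMParams(0, 0.4, 1, 1))
        assert math.isnan(power_exemplary(q))


class TestPowerGrid:
    def test_monotone_in_paired_fraction(self):
        """Power is nondecreasing in the paired fraction (>= 0.1) and
        q=1 beats q=0, for appreciable confounding strengths."""
        fractions = [0.0, 0.1, 0.25, 0.5, 0.75, 1.0]
        g = power_grid([50, 100], fractions, [1.0, 1.5, 2.5], "count")
        gc = power_grid([50, 100], fractions, [0.25, 0.75, 1.5], "continuous")
        for grid in (g, gc):
            assert np.all(np.diff(grid.power[:, 1:, :], axis=1) >= -1e-12)
            assert np.all(grid.power[:, -1, :] > grid.power[:, 0, :])

    def test_monotone_decreasing_in_strength_when_unpaired(self):
        g = power_grid([100], [0.0], [0.25, 0.5, 1.0, 1.5], "continuous")
        assert np.all(np.diff(g.power[0, 0, :]) < 0)

    def test_low_pairing_dip_exists(self):
        """At small N and near-zero confounding, a fraction near 0.05
        has strictly lower power than no pairing at all (the df cost)."""
        for family, n, strength in [("count", 50, 0.5), ("continuous", 20, 0.002)]:
            g = power_grid([n], [0.0, 0.04, 0.05, 0.06, 0.08], [strength], family)
            p0 = g.power[0, 0, 0]
            assert np.nanmin(g.power[0, 1:, 0]) < p0

    def test_paired_half_n_beats_unpaired_n(self):
        """Fully paired with N/2 subjects outpowers fully unpaired with
        N samples whenever sigma2_subj > sigma2_err (closed forms)."""
        for n in (20, 50, 100):
            for s2e in (0.3, 1.0):
                for ratio in (1.05, 1.5, 3.0):
                    s2s = ratio * s2e
                    for d in (0.2, 0.41):
                        pp = power_exemplary(PowerQuery(
                            DesignSpec(n, 1.0), "continuous", LMMParams(0, d, s2s, s2e)))
                        pu = power_exemplary(PowerQuery(
                            DesignSpec(n, 0.0), "continuous", LMMParams(0, d, s2s, s2e)))
                        assert pp >= pu
                        if pu < 1.0 - 1e-12:
                            assert pp > pu

    def test_grid_frame_round_trip(self, tmp_path):
        g = power_grid([20], [0.0, 1.0], [0.5, 1.0], "continuous", fold_change=1.5)
        frame = g.to_frame()
        assert len(frame) == 4
        assert set(frame.columns) == {"n", "fraction", "strength", "power"}
        g.to_tsv(tmp_path / "grid.tsv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "grid.tsv", sep="\t")
        assert np.allclose(back["power"], frame["power"], equal_nan=True)

    def test_axes_validated(self):
        from pairpower import PowerGrid

        with pytest.raises(ValidationError):
            PowerGrid(np.array([2, 1]), np.array([0.5]), np.array([1.0]),
                      np.zeros((2, 1, 1)), 0.05, "continuous", 1.5)
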