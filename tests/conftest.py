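import math

import numpy as np
import pandas as pd
import pytest

from pairpower import DesignSpec, SampleTable, build_design


@pytest.fixture
def paired_table():
    """Fully paired design with 10 subjects (20 samples)."""
    return build_design(DesignSpec(20, 1.0))


@pytest.fixture
def mixed_table():
    """Mixed design: 5 paired subjects + 5 unpaired per arm (20 samples)."""
    return build_design(DesignSpec(20, 1.0 / 3.0))


@pytest.fixture
def tiny_paired_table():
    return SampleTable(
        pd.DataFrame(
            {
                "subject_id": ["A", "A", "B", "C"],
                "condition": ["tumor", "normal", "tumor", "normal"],
                "offset": [0.0, 0.0, 0.0, 0.0],
            }
        )
    )


def simulate_lmm(table, mu, delta, sigma2_subj, sigma2_err, rng):
    """Draw one feature from the random-intercept LMM on a table."""
    codes = table.data["subject_id"].astype("category").cat.codes.to_numpy()
    t = table.treatment_indicator()
    b = rng.normal(0.0, math.sqrt(sigma2_subj), table.n_subjects)
    return mu + delta * t + b[codes] + rng.normal(0.0, math.sqrt(sigma2_err), len(t))


def simulate_nb(table, mu, delta, sigma2_subj, scale, rng):
    """Draw one feature of NB counts (gamma-Poisson) on a table."""
    codes = table.data["subject_id"].astype("category").cat.codes.to_numpy()
    t = table.treatment_indicator()
    b = rng.normal(0.0, math.sqrt(sigma2_subj), table.n_subjects)
    lam = np.exp(mu + delta * t + b[codes] + table.offsets())
    theta = 1.0 / scale**2
    return rng.poisson(rng.gamma(theta, lam / theta)).astype(float)
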