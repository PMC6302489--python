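"""Simulation-based power and FDR evaluation.

The simulation method draws many per-feature datasets under the
generative mixed models, fits the matching model to each feature,
adjusts p-values by Benjamini-Hochberg within each simulated feature
set, and summarizes statistical power (proportion of truly
differentially expressed features rejected) and realized FDR (false
rejections over rejections, zero when nothing is rejected), averaged
over replicates.

Randomness is counter-based: every (replicate, feature) pair owns a
substream derived from the master seed, so results do not depend on
iteration order and are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .design import DesignSpec, SampleTable, build_design
from .errors import ValidationError
from .models import bh_adjust, fit_lmm, fit_nb_glmm
from .power import (
    DEFAULT_BASELINE_COUNT,
    DEFAULT_SCALE,
    PowerQuery,
    continuous_sigma2_err,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimSettings:
    """One simulation configuration.

    Defaults mirror the reference simulation protocol for continuous
    data: 1000 biomarkers per replicate of which 20 are differentially
    expressed with |TRT| effects drawn uniformly between 1 and 2, BH
    at FDR 0.05 within each replicate, 100 replicates.  ``sigma2_err``
    of None couples the residual variance to ``sigma2_subj`` through
    the default slope (1.73, floored); passing a number fixes it.
    ``effect_signs`` of "positive" gives all-positive effects (power
    of the two-sided test is symmetric in the sign); "random" flips a
    fair coin per effect.
    """

    design: DesignSpec
    family: str = "continuous"
    n_biomarkers: int = 1000
    n_de: int = 20
    effect_low: float = 1.0
    effect_high: float = 2.0
    sigma2_subj: float = 1.0
    sigma2_err: float | None = None
    scale: float = DEFAULT_SCALE
    baseline_mean_count: float = DEFAULT_BASELINE_COUNT
    fdr_level: float = 0.05
    n_reps: int = 100
    seed: int = 0
    effect_signs: str = "positive"
    n_quad: int = 15

    def __post_init__(self) -> None:
        if self.family not in ("continuous", "count"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.n_biomarkers < 1:
            raise ValidationError("n_biomarkers must be positive")
        if not (0 <= self.n_de <= self.n_biomarkers):
            raise ValidationError("need 0 <= n_de <= n_biomarkers")
        if self.effect_low > self.effect_high:
            raise ValidationError("effect_low must be <= effect_high")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValidationError("fdr_level must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be positive")
        if self.sigma2_subj < 0:
            raise ValidationError("sigma2_subj must be >= 0")
        if self.effect_signs not in ("positive", "random"):
            raise ValidationError("effect_signs must be 'positive' or 'random'")

    @property
    def resolved_sigma2_err(self) -> float:
        if self.sigma2_err is not None:
            return self.sigma2_err
        return continuous_sigma2_err(self.sigma2_subj)


@dataclass
class SimResult:
    """Averaged power/FDR over replicates, with per-replicate detail."""

    mean_power: float
    mean_fdr: float
    per_rep_power: np.ndarray
    per_rep_fdr: np.ndarray
    settings: SimSettings
    n_failed_fits: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": np.arange(len(self.per_rep_power)),
                "power": self.per_rep_power,
                "fdr": self.per_rep_fdr,
            }
        )


def _rep_rng(seed: int, rep_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, rep_index, stream)))


def _feature_rng(seed: int, rep_index: int, feature: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, rep_index, 1, feature)))


def _simulate_one_feature(
    rng: np.random.Generator,
    table: SampleTable,
    subj_codes: np.ndarray,
    n_subjects: int,
    family: str,
    delta: float,
    sigma2_subj: float,
    sigma2_err: float,
    scale: float,
    baseline_mean_count: float,
    mu: float = 0.0,
) -> np.ndarray:
    t = table.treatment_indicator()
    b = rng.normal(0.0, math.sqrt(sigma2_subj), n_subjects) if sigma2_subj > 0 else np.zeros(n_subjects)
    eta = mu + delta * t + b[subj_codes]
    if family == "continuous":
        return eta + rng.normal(0.0, math.sqrt(sigma2_err), len(t))
    lam = baseline_mean_count * np.exp(eta + table.offsets())
    theta = 1.0 / scale**2
    # gamma-Poisson mixture = NB, valid for non-integer theta
    return rng.poisson(rng.gamma(theta, lam / theta)).astype(float)


def simulate_feature_set(settings: SimSettings, rep_index: int):
    """One replicate: an (n_biomarkers x N) matrix plus truth labels.

    The replicate's differentially expressed features and their
    effects are drawn from a replicate-level stream; each feature's
    subject effects and noise come from its own (seed, rep, feature)
    substream, so the output is bit-identical for fixed inputs.

    Returns ``(matrix, truth)`` where ``truth`` is a DataFrame with
    columns ``feature``, ``delta``, ``is_de``.
    """
    table = build_design(settings.design)
    subj = table.data["subject_id"]
    codes = subj.astype("category").cat.codes.to_numpy()
    n_subjects = table.n_subjects

    rng_rep = _rep_rng(settings.seed, rep_index)
    de_idx = np.sort(rng_rep.choice(settings.n_biomarkers, settings.n_de, replace=False))
    effects = rng_rep.uniform(settings.effect_low, settings.effect_high, settings.n_de)
    if settings.effect_signs == "random":
        effects *= rng_rep.choice([-1.0, 1.0], settings.n_de)
    deltas = np.zeros(settings.n_biomarkers)
    deltas[de_idx] = effects

    s2e = settings.resolved_sigma2_err
    mat = np.empty((settings.n_biomarkers, table.n_samples))
    for f in range(settings.n_biomarkers):
        rng = _feature_rng(settings.seed, rep_index, f)
        mat[f] = _simulate_one_feature(
            rng,
            table,
            codes,
            n_subjects,
            settings.family,
            deltas[f],
            settings.sigma2_subj,
            s2e,
            settings.scale,
            settings.baseline_mean_count,
        )
    truth = pd.DataFrame(
        {
            "feature": np.arange(settings.n_biomarkers),
            "delta": deltas,
            "is_de": deltas != 0.0,
        }
    )
    return mat, truth


def _fit_feature(y, table: SampleTable, family: str, include_random: bool, n_quad: int):
    if family == "continuous":
        return fit_lmm(y, table, include_random=include_random)
    return fit_nb_glmm(y, table, include_random=include_random, n_quad=n_quad)


def run_simulation(settings: SimSettings) -> SimResult:
    """Run the full simulation and summarize power and realized FDR.

    Per replicate: fit the family's model to every feature (the
    subject random effect is included exactly when the design has at
    least one paired subject), BH-adjust the per-feature p-values at
    ``fdr_level``, and record power = (true DE rejected) / n_de and
    FDR = (null rejected) / max(1, rejected).  Features whose fits
    fail are excluded from numerator and denominator and counted in
    ``n_failed_fits``.
    """
    table = build_design(settings.design)
    include_random = table.n_paired_subjects > 0
    per_power = np.full(settings.n_reps, np.nan)
    per_fdr = np.full(settings.n_reps, np.nan)
    n_failed = 0
    for rep in range(settings.n_reps):
        mat, truth = simulate_feature_set(settings, rep)
        pvals = np.full(settings.n_biomarkers, np.nan)
        for f in range(settings.n_biomarkers):
            try:
                res = _fit_feature(mat[f], table, settings.family, include_random,
                                   settings.n_quad)
            except Exception:  # noqa: BLE001 - any fit failure counts as failed
                res = None
            if res is not None and res.converged and math.isfinite(res.p_value):
                pvals[f] = res.p_value
        ok = ~np.isnan(pvals)
        n_failed += int((~ok).sum())
        if not ok.any():
            logger.warning("replicate %d: all fits failed", rep)
            continue
        padj = bh_adjust(pvals)
        rej = (padj <= settings.fdr_level) & ok
        is_de = truth["is_de"].to_numpy()
        n_true_avail = int((is_de & ok).sum())
        if settings.n_de > 0 and n_true_avail > 0:
            per_power[rep] = (rej & is_de).sum() / n_true_avail
        elif settings.n_de == 0:
            per_power[rep] = np.nan
        per_fdr[rep] = (rej & ~is_de).sum() / max(1, rej.sum())
    mean_power = float(np.nanmean(per_power)) if np.isfinite(per_power).any() else math.nan
    mean_fdr = float(np.nanmean(per_fdr)) if np.isfinite(per_fdr).any() else math.nan
    return SimResult(mean_power, mean_fdr, per_power, per_fdr, settings, n_failed)


def simulate_test_power(
    query: PowerQuery,
    n_sims: int,
    seed: int = 0,
    n_quad: int = 15,
) -> tuple[float, float]:
    """Monte-Carlo power of the per-feature test at level alpha.

    Independent check of :func:`pairpower.power.power_exemplary`:
    simulate ``n_sims`` single features under the query's model and
    design, fit the matching model (random effect included exactly
    when the design has paired subjects), and return the rejection
    rate at ``query.alpha`` with its binomial Monte-Carlo standard
    error.  Failed fits are excluded.
    """
    table = build_design(query.design)
    include_random = table.n_paired_subjects > 0
    codes = table.data["subject_id"].astype("category").cat.codes.to_numpy()
    n_subjects = table.n_subjects
    p = query.params
    if query.family == "continuous":
        kwargs = dict(sigma2_err=p.sigma2_err, scale=1.0, baseline_mean_count=1.0)
    else:
        kwargs = dict(sigma2_err=1.0, scale=p.scale,
                      baseline_mean_count=query.baseline_mean_count)
    n_rej = 0
    n_ok = 0
    for i in range(n_sims):
        rng = _feature_rng(seed, 0, i)
        y = _simulate_one_feature(
            rng, table, codes, n_subjects, query.family, p.delta, p.sigma2_subj,
            mu=0.0, **kwargs,
        )
        try:
            res = _fit_feature(y, table, query.family, include_random, n_quad)
        except Exception:  # noqa: BLE001
            continue
        if res.converged and math.isfinite(res.p_value):
            n_ok += 1
            if res.p_value <= query.alpha:
                n_rej += 1
    if n_ok == 0:
        return math.nan, math.nan
    phat = n_rej / n_ok
    se = math.sqrt(max(phat * (1.0 - phat), 1.0 / n_ok) / n_ok)
    return phat, se
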