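"""Paired vs unpaired analysis comparison on one expression dataset.

The demonstration pipeline analyzes the same cohort under five
variants and contrasts their discoveries:

* **paired** — the mixed model with the subject random effect on a
  core set of paired subjects (both samples each);
* **unpaired1** — the *same samples*, dropping the random effect
  (ignoring the pairing): any difference in discoveries is
  attributable to the model, not the data;
* **unpaired2** — a genuinely unpaired sample set of the same size in
  which no subject contributes two samples, built by the two-stage
  subsampling rule below;
* **unpaired1_cov / unpaired2_cov** — the unpaired analyses with
  subject-level covariates as fixed effects in place of the random
  effect.

Per variant, every gene is fitted, p-values are BH-adjusted across
genes, discoveries are counted at an FDR threshold, and fold-change
exceedance curves (proportion of genes with |log FC| above each
threshold) summarize effect-size attenuation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleTable
from .errors import ValidationError
from .models import bh_adjust, fit_lmm, fit_nb_glmm

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLDS = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0)


@dataclass(frozen=True)
class ComparisonPlan:
    """Configuration of the comparison pipeline."""

    n_core_subjects: int = 100
    fdr_threshold: float = 0.01
    covariate_names: tuple[str, ...] | None = None
    seed: int = 0
    fc_thresholds: tuple[float, ...] = DEFAULT_FC_THRESHOLDS

    def __post_init__(self) -> None:
        if self.n_core_subjects < 2 or self.n_core_subjects % 2:
            raise ValidationError("n_core_subjects must be an even integer >= 2")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if any(th < 1.0 for th in self.fc_thresholds):
            raise ValidationError("fold-change thresholds must be at least 1")
        if list(self.fc_thresholds) != sorted(self.fc_thresholds):
            raise ValidationError("fc_thresholds must be increasing")


@dataclass
class ComparisonResult:
    """Per-gene results and summaries for all analysis variants."""

    table: pd.DataFrame
    n_significant: dict[str, int]
    fc_exceedance: pd.DataFrame  # index: threshold, columns: variants
    n_failed: dict[str, int]
    fdr_threshold: float


def _pools(cohort: SampleTable):
    data = cohort.data
    counts = data.groupby("subject_id", sort=False)["condition"].agg(list)
    treat = cohort.treatment_label
    paired = [s for s, conds in counts.items() if len(conds) == 2]
    tumor_only = [s for s, conds in counts.items() if conds == [treat]]
    normal_only = [
        s for s, conds in counts.items() if len(conds) == 1 and conds[0] != treat
    ]
    return paired, tumor_only, normal_only


def select_core_subjects(cohort: SampleTable, plan: ComparisonPlan) -> list[str]:
    """The core paired subjects shared by the paired and unpaired-1 analyses."""
    paired, _, _ = _pools(cohort)
    if len(paired) < plan.n_core_subjects:
        raise ValidationError(
            f"cohort has {len(paired)} paired subjects, "
            f"need {plan.n_core_subjects} for the core set"
        )
    rng = np.random.default_rng(np.random.SeedSequence((plan.seed, 10)))
    return sorted(rng.choice(paired, plan.n_core_subjects, replace=False).tolist())


def _rows_for(cohort: SampleTable, subjects, condition=None) -> np.ndarray:
    data = cohort.data
    mask = data["subject_id"].isin(set(subjects))
    if condition is not None:
        mask &= data["condition"] == condition
    return np.flatnonzero(mask.to_numpy())


def make_unpaired_design2(
    cohort: SampleTable,
    plan: ComparisonPlan,
    core_subjects: list[str] | None = None,
) -> SampleTable:
    """Fully unpaired sample set by the two-stage subsampling rule.

    Stage 1: half of the core paired subjects are randomly assigned to
    contribute only their tumor sample, the other half only their
    normal sample.  Stage 2: from the subjects outside the core,
    another half-core of tumor-only samples is drawn from the pool of
    tumor-only subjects plus unselected paired subjects, and a
    half-core of normal-only samples from the normal-only subjects
    plus the still-unselected paired subjects.  The result has
    ``2 * n_core_subjects`` samples from as many distinct subjects.
    """
    paired, tumor_only, normal_only = _pools(cohort)
    if core_subjects is None:
        core_subjects = select_core_subjects(cohort, plan)
    h = plan.n_core_subjects // 2
    rng = np.random.default_rng(np.random.SeedSequence((plan.seed, 11)))
    treat, ctrl = cohort.condition_labels

    core = list(core_subjects)
    core_tumor = sorted(rng.choice(core, h, replace=False).tolist())
    core_normal = [s for s in core if s not in set(core_tumor)]

    non_core_paired = [s for s in paired if s not in set(core)]
    pool_tumor = tumor_only + non_core_paired
    if len(pool_tumor) < h:
        raise ValidationError(
            f"tumor-only pool has {len(pool_tumor)} subjects "
            f"(tumor-only plus unselected paired), need {h}"
        )
    extra_tumor = sorted(rng.choice(pool_tumor, h, replace=False).tolist())
    remaining_paired = [s for s in non_core_paired if s not in set(extra_tumor)]
    pool_normal = normal_only + remaining_paired
    if len(pool_normal) < h:
        raise ValidationError(
            f"normal-only pool has {len(pool_normal)} subjects "
            f"(normal-only plus still-unselected paired), need {h}"
        )
    extra_normal = sorted(rng.choice(pool_normal, h, replace=False).tolist())

    rows = np.concatenate(
        [
            _rows_for(cohort, core_tumor + extra_tumor, treat),
            _rows_for(cohort, core_normal + extra_normal, ctrl),
        ]
    )
    table = cohort.subset(rows)
    if table.n_paired_subjects:
        raise ValidationError("unpaired design 2 selection produced a paired subject")
    return table


def _analyze_variant(
    matrix: pd.DataFrame,
    table: SampleTable,
    family: str,
    include_random: bool,
    covariates,
    n_quad: int,
):
    sample_ids = table.data["sample_id"].tolist()
    sub = matrix[sample_ids]
    deltas = np.full(len(matrix), np.nan)
    pvals = np.full(len(matrix), np.nan)
    n_failed = 0
    for g in range(len(matrix)):
        y = sub.iloc[g].to_numpy(dtype=float)
        try:
            if family == "continuous":
                res = fit_lmm(y, table, include_random=include_random)
            else:
                res = fit_nb_glmm(
                    y, table, include_random=include_random,
                    covariates=covariates, n_quad=n_quad,
                )
        except Exception:  # noqa: BLE001
            res = None
        if res is not None and res.converged and math.isfinite(res.p_value):
            deltas[g] = res.delta
            pvals[g] = res.p_value
        else:
            n_failed += 1
    return deltas, pvals, n_failed


def run_comparison(
    matrix: pd.DataFrame,
    cohort: SampleTable,
    plan: ComparisonPlan,
    family: str = "count",
    n_quad: int = 15,
) -> ComparisonResult:
    """Run all analysis variants on one gene x sample matrix.

    ``matrix`` columns must cover every sample id used by the
    variants' tables.  Genes whose fit fails in one variant are
    dropped from that variant only (counts reported per variant).
    Fold changes are the model coefficients ``exp(delta_hat)``;
    exceedance is computed on ``|delta_hat|`` so up- and
    down-regulation both count.
    """
    if "sample_id" not in cohort.data.columns:
        raise ValidationError("cohort table must carry a sample_id column")
    missing = set(cohort.data["sample_id"]) - set(matrix.columns)
    if missing:
        raise ValidationError(f"matrix lacks columns for samples {sorted(missing)[:5]}")

    core = select_core_subjects(cohort, plan)
    paired_rows = _rows_for(cohort, core)
    paired_table = cohort.subset(paired_rows)
    u2_table = make_unpaired_design2(cohort, plan, core_subjects=core)
    # unpaired design 1 reuses the exact samples of the paired analysis
    assert set(paired_table.data["sample_id"]) == set(
        cohort.data.loc[paired_rows, "sample_id"]
    )

    variants: list[tuple[str, SampleTable, bool, tuple[str, ...] | None]] = [
        ("paired", paired_table, True, None),
        ("unpaired1", paired_table, False, None),
        ("unpaired2", u2_table, False, None),
    ]
    if plan.covariate_names:
        variants.append(("unpaired1_cov", paired_table, False, tuple(plan.covariate_names)))
        variants.append(("unpaired2_cov", u2_table, False, tuple(plan.covariate_names)))

    out = pd.DataFrame(index=matrix.index)
    n_significant: dict[str, int] = {}
    n_failed: dict[str, int] = {}
    exceed = {}
    for name, table, include_random, covs in variants:
        deltas, pvals, failed = _analyze_variant(
            matrix, table, family, include_random, covs, n_quad
        )
        padj = bh_adjust(pvals)
        out[f"delta_{name}"] = deltas
        out[f"fold_change_{name}"] = np.exp(deltas)
        out[f"p_{name}"] = pvals
        out[f"padj_{name}"] = padj
        n_significant[name] = int(np.nansum(padj <= plan.fdr_threshold))
        n_failed[name] = failed
        ok = ~np.isnan(deltas)
        exceed[name] = [
            float(np.mean(np.abs(deltas[ok]) >= math.log(th))) if ok.any() else math.nan
            for th in plan.fc_thresholds
        ]
        logger.info("variant %s: %d significant at FDR %g, %d failed fits",
                    name, n_significant[name], plan.fdr_threshold, failed)
    fc_exceedance = pd.DataFrame(
        exceed, index=pd.Index(plan.fc_thresholds, name="fc_threshold")
    )
    return ComparisonResult(
        table=out.reset_index(),
        n_significant=n_significant,
        fc_exceedance=fc_exceedance,
        n_failed=n_failed,
        fdr_threshold=plan.fdr_threshold,
    )
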