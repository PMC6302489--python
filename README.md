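# pairpower

**Statistical power of paired samples in differential-expression
study designs.**

When a genomics team plans a two-condition expression study — tumor
vs adjacent normal tissue, say — and can afford `N` samples, it must
decide how many subjects will contribute *paired* samples (one under
each condition) and how many a single sample.  Subject-level
confounders (diet, lifestyle, genetics, sample handling) shift both
of a subject's samples together; pairing lets the analysis estimate
them out.  `pairpower` quantifies what that choice is worth, for both
count (RNA-Seq-like) and continuous (microarray-like) expression
data.

Per feature, expression follows a mixed model with a fixed treatment
effect and a random subject intercept:

    continuous:  Y_ij = mu + TRT_i + Subj_j + eps_ij
    count:       log E[Y_ij] = log N_ij + mu + TRT_i + Subj_j,
                 Y_ij | Subj_j ~ NegBin(mean m_ij, dispersion theta)

with `Subj_j ~ N(0, sigma2_subj)` quantifying confounding strength
and `TRT` the natural-log fold change (`delta`).  The package
provides:

- **`design`** — balanced designs with a target fraction `q` of
  paired subjects (`P = round(qN/(1+q))` paired, the rest split
  evenly between arms);
- **`models`** — per-feature ML fits: exact-marginal-likelihood LMM
  and adaptive Gauss–Hermite NB-GLMM, their no-random-effect
  (unpaired-analysis) variants, Wald tests of `delta` with
  denominator df `N - 2 - P` (one df per estimated subject effect),
  and Benjamini–Hochberg adjustment;
- **`power`** — the analytic *exemplary-data* method:
  `Var(delta_hat)` by GLS under the design's covariance, noncentral-F
  power `P(F(1, N-2-P, delta^2/Var) > F_crit)`, evaluated over
  design × confounding grids;
- **`simulate`** — the simulation method: many feature sets drawn
  under the models, fitted, BH-adjusted, summarized as mean power and
  realized FDR;
- **`datagen`** — synthetic cohorts with the motivating study's
  structure (paired/tumor-only/normal-only subjects, published
  covariate marginals, log-normal library sizes) and per-gene
  parameters in the empirically observed ranges;
- **`comparison`** — the paired vs unpaired demonstration: the same
  matrix analyzed paired, unpaired-on-the-same-samples, and on a
  genuinely unpaired subsample, with discovery counts and
  fold-change exceedance curves.

## Worked example

How much power does full pairing buy at N = 100 samples when
subject-level confounding is as strong as the noise floor
(`sigma2_subj = 1`, `sigma2_err = 1.73`), for a 1.5-fold change?

```python
from pairpower import DesignSpec, LMMParams, PowerQuery, power_exemplary

params = LMMParams(mu=0.0, delta=0.41, sigma2_subj=1.0, sigma2_err=1.73)
for q in (0.0, 0.5, 1.0):
    query = PowerQuery(DesignSpec(100, q), "continuous", params)
    print(f"paired fraction {q:.1f}: power {power_exemplary(query):.3f}")
```

```
paired fraction 0.0: power 0.233
paired fraction 0.5: power 0.301
paired fraction 1.0: power 0.333
```

Fully pairing the cohort raises power from 0.23 to 0.33 at the same
budget — and the gap widens with stronger confounding.  The
simulation route confirms the analytic numbers and adds FDR control:

```sh
pairpower simulate --family continuous --n 100 --paired-fraction 1.0 \
    --sigma2-subj 1.0 --sigma2-err 1.73 --biomarkers 500 --n-de 20 \
    --reps 20 --seed 42 --out sim.tsv
```

```
mean power 0.9600, mean FDR 0.0537
```

With 20 of 500 biomarkers truly differentially expressed (effects
U(1,2)), nearly all are detected and the realized FDR stays within
Monte-Carlo error of the nominal 0.05 (per-replicate FDR has a
standard error of about 0.01 at 20 replicates).  Other subcommands: `power-grid` (contour
grids), `generate-data` (synthetic cohorts and matrices),
`compare-designs` (paired vs unpaired pipeline), `fit` (per-gene
fits on your own matrix + sample sheet).

See `docs/methods.md` for the models, the df accounting behind the
low-pairing power dip, default parameter provenance, and known
limitations.

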