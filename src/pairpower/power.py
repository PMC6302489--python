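"""Analytic power approximation from an exemplary dataset.

The "probability distribution" (exemplary-data) method evaluates the
power of the Wald test of the treatment effect in a mixed model
without simulation: build the design's covariance structure at the
assumed variance components, compute the generalized-least-squares
variance of the treatment contrast, form the noncentrality parameter
``ncp = delta^2 / Var(delta_hat)``, and evaluate the tail of a
noncentral F distribution with 1 numerator df and denominator df
``N - 2 - P`` (each of the ``P`` paired subjects' estimated random
effects costs one residual degree of freedom; this is what produces
the small dip in power when only ~5% of subjects are paired).

For the count family the covariance is a working covariance on the
link (log) scale at random effect zero: per-observation variance
``1/m + k + sigma2_subj`` and within-subject covariance
``sigma2_subj``, where ``m`` is the expected count under the
delta-method linearization of the log link and ``k = scale^2`` is the
NB dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, SampleTable, build_design, n_paired_subjects
from .errors import NumericalError, ValidationError
from .models import LMMParams, NBParams

#: default test size for power evaluation
DEFAULT_ALPHA = 0.05
#: slope tying the residual variance to the subject variance in the
#: continuous family, estimated from the miRNA fits of the motivating
#: colorectal-cancer study
SIGMA2_SLOPE = 1.73
#: additive floor keeping sigma2_err positive when sigma2_subj = 0
SIGMA2_FLOOR = 0.05
#: default NB scale sqrt(k) (average over significant genes in the
#: motivating RNA-Seq fits)
DEFAULT_SCALE = 1.15
#: default fold changes: subtle RNA-Seq target and microarray target
DEFAULT_FC_COUNT = 1.25
DEFAULT_FC_CONTINUOUS = 1.5
#: default baseline expected count per sample for the count family
DEFAULT_BASELINE_COUNT = 100.0

FAMILIES = ("continuous", "count")


def log_fold_change(fold_change: float) -> float:
    """Natural-log fold change (the TRT effect delta) for a fold change."""
    if fold_change <= 0:
        raise ValidationError(f"fold change must be positive, got {fold_change}")
    return math.log(fold_change)


@dataclass(frozen=True)
class PowerQuery:
    """One power evaluation: a design, a family and its parameters."""

    design: DesignSpec
    family: str
    params: Union[LMMParams, NBParams]
    alpha: float = DEFAULT_ALPHA
    baseline_mean_count: float = DEFAULT_BASELINE_COUNT

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "continuous" and not isinstance(self.params, LMMParams):
            raise ValidationError("continuous family requires LMMParams")
        if self.family == "count" and not isinstance(self.params, NBParams):
            raise ValidationError("count family requires NBParams")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.baseline_mean_count <= 0:
            raise ValidationError("baseline_mean_count must be positive")


def gls_var_delta(
    table: SampleTable,
    family: str,
    params: Union[LMMParams, NBParams],
    baseline_mean_count: float = DEFAULT_BASELINE_COUNT,
) -> float:
    """GLS variance of the treatment contrast under known covariance.

    Continuous family: marginal covariance of the LMM (2x2
    compound-symmetry blocks for pairs).  Count family: working
    covariance on the log scale at random effect zero, with expected
    counts ``m = baseline_mean_count * exp(offset - median offset) *
    exp(delta)`` under treatment.
    """
    t = table.treatment_indicator()
    pairs = table.pair_indices()
    singles = table.single_indices()
    if t.sum() in (0, len(t)):
        raise ValidationError("both conditions must be present")

    if family == "continuous":
        s2s = params.sigma2_subj
        v = np.full(len(t), s2s + params.sigma2_err)
    elif family == "count":
        s2s = params.sigma2_subj
        k = params.k
        off = table.offsets()
        rel = off - np.median(off)
        m = baseline_mean_count * np.exp(rel + params.delta * t)
        v = 1.0 / m + k + s2s
    else:
        raise ValidationError(f"unknown family {family!r}")

    A = np.zeros((2, 2))
    if singles.size:
        w = 1.0 / v[singles]
        ts = t[singles]
        A[0, 0] += w.sum()
        A[0, 1] += (w * ts).sum()
        A[1, 1] += (w * ts).sum()
    if len(pairs):
        i1, i2 = pairs[:, 0], pairs[:, 1]
        v1, v2, c = v[i1], v[i2], s2s
        det = v1 * v2 - c * c
        if np.any(det <= 0):
            raise NumericalError("non-positive-definite working covariance")
        w11, w22, w12 = v2 / det, v1 / det, -c / det
        t1, t2 = t[i1], t[i2]
        A[0, 0] += (w11 + w22 + 2.0 * w12).sum()
        A[0, 1] += (w11 * t1 + w22 * t2 + w12 * (t1 + t2)).sum()
        A[1, 1] += (w11 * t1 * t1 + w22 * t2 * t2 + 2.0 * w12 * t1 * t2).sum()
    A[1, 0] = A[0, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if not np.isfinite(det) or det <= 1e-300 * max(A[0, 0], 1.0):
        raise NumericalError("singular GLS system for the treatment contrast")
    return float(A[0, 0] / det)


def power_exemplary(query: PowerQuery) -> float:
    """Approximate power for one design/parameter combination.

    Returns NaN ("missing") when the denominator degrees of freedom
    drop below 1 or the working covariance is numerically singular —
    the analogue of the blank low-pairing regions in the published
    contour plots.
    """
    spec = query.design
    table = build_design(spec)
    p = n_paired_subjects(spec)
    ddf = spec.n_samples_total - 2 - p
    if ddf < 1:
        return math.nan
    try:
        var = gls_var_delta(table, query.family, query.params, query.baseline_mean_count)
    except NumericalError:
        return math.nan
    ncp = query.params.delta**2 / var
    fcrit = stats.f.ppf(1.0 - query.alpha, 1, ddf)
    if ncp < 1e-12:  # central F: power equals the test size
        return float(stats.f.sf(fcrit, 1, ddf))
    return float(min(max(stats.ncf.sf(fcrit, 1, ddf, ncp), 0.0), 1.0))


@dataclass
class PowerGrid:
    """Power over a (sample size) x (paired fraction) x (strength) grid.

    ``strengths`` is the confounder-strength axis: raw ``sigma2_subj``
    for the continuous family, the tenth root of ``sigma2_subj`` for
    the count family (the scale on which the motivating study
    visualized its count-data fits).  Missing cells (no power
    approximation available) are NaN.
    """

    ns: np.ndarray
    fractions: np.ndarray
    strengths: np.ndarray
    power: np.ndarray  # shape (len(ns), len(fractions), len(strengths))
    alpha: float
    family: str
    fold_change: float

    def __post_init__(self) -> None:
        self.ns = np.asarray(self.ns)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        for axis, name in ((self.ns, "ns"), (self.fractions, "fractions"),
                           (self.strengths, "strengths")):
            if axis.size == 0:
                raise ValidationError(f"{name} axis is empty")
            if axis.size > 1 and not np.all(np.diff(axis) > 0):
                raise ValidationError(f"{name} axis must be strictly increasing")
        finite = self.power[np.isfinite(self.power)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("power values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (n, fraction, strength, power)."""
        nn, ff, ss = np.meshgrid(self.ns, self.fractions, self.strengths, indexing="ij")
        return pd.DataFrame(
            {
                "n": nn.ravel(),
                "fraction": ff.ravel(),
                "strength": ss.ravel(),
                "power": self.power.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def plot_contours(self, path=None):  # pragma: no cover - plotting
        """Contour plot per sample size (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(self.ns), figsize=(4 * len(self.ns), 3.2),
                                 squeeze=False)
        for ax, (i, n) in zip(axes[0], enumerate(self.ns)):
            cs = ax.contourf(self.fractions, self.strengths, self.power[i].T, levels=10)
            fig.colorbar(cs, ax=ax)
            ax.set_xlabel("proportion of subjects with paired samples")
            ax.set_ylabel("confounder strength")
            ax.set_title(f"N = {n} ({self.family})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def continuous_sigma2_err(sigma2_subj: float, slope: float = SIGMA2_SLOPE,
                          floor: float = SIGMA2_FLOOR) -> float:
    """Default residual variance coupled to the subject variance.

    The motivating study's per-miRNA fits showed the residual variance
    roughly proportional to the subject variance (slope 1.73); the
    floor keeps zero-confounding cells well-posed.
    """
    return max(slope * sigma2_subj, floor)


def power_grid(
    ns,
    fractions,
    strengths,
    family: str,
    fold_change: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    scale: float = DEFAULT_SCALE,
    baseline_mean_count: float = DEFAULT_BASELINE_COUNT,
    sigma2_slope: float = SIGMA2_SLOPE,
    sigma2_floor: float = SIGMA2_FLOOR,
    condition_labels=("tumor", "normal"),
) -> PowerGrid:
    """Evaluate :func:`power_exemplary` over a design grid.

    ``strengths`` follows the family's axis convention (see
    :class:`PowerGrid`).  Default fold changes: 1.25 for counts
    (delta = ln 1.25 = 0.22) and 1.5 for continuous data
    (delta = ln 1.5 = 0.41).
    """
    if family not in FAMILIES:
        raise ValidationError(f"family must be one of {FAMILIES}")
    if fold_change is None:
        fold_change = DEFAULT_FC_COUNT if family == "count" else DEFAULT_FC_CONTINUOUS
    delta = log_fold_change(fold_change)
    ns = np.asarray(list(ns))
    fractions = np.asarray(list(fractions), dtype=float)
    strengths = np.asarray(list(strengths), dtype=float)
    power = np.full((ns.size, fractions.size, strengths.size), np.nan)
    for i, n in enumerate(ns):
        for j, q in enumerate(fractions):
            spec = DesignSpec(int(n), float(q), condition_labels)
            for s, strength in enumerate(strengths):
                if family == "continuous":
                    s2s = float(strength)
                    params = LMMParams(
                        mu=0.0,
                        delta=delta,
                        sigma2_subj=s2s,
                        sigma2_err=continuous_sigma2_err(s2s, sigma2_slope, sigma2_floor),
                    )
                else:
                    s2s = float(strength) ** 10
                    params = NBParams(mu=0.0, delta=delta, sigma2_subj=s2s, scale=scale)
                power[i, j, s] = power_exemplary(
                    PowerQuery(spec, family, params, alpha, baseline_mean_count)
                )
    return PowerGrid(ns, fractions, strengths, power, alpha, family, fold_change)
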