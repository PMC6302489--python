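"""Study designs with a mix of paired and unpaired subjects.

A design allocates ``N`` expression samples between two conditions
(by default ``"tumor"`` and ``"normal"``).  A *paired* subject
contributes one sample under each condition; unpaired subjects
contribute a single sample and are split evenly between the two arms,
which is the balanced allocation that maximizes power for a fixed
total number of samples.

The central quantity is the paired-subject fraction ``q``: the target
proportion of *subjects* (not samples) who contribute paired samples.
With ``P`` paired subjects and ``U`` unpaired subjects per arm the
sample count is ``2P + 2U = N`` and the subject count is
``S = P + 2U``, so the number of paired subjects solving
``P / S = q`` for a fixed ``N`` is ``P = q N / (1 + q)``, rounded
half-up to an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_CONDITIONS: tuple[str, str] = ("tumor", "normal")

#: Columns every sample table carries; covariates are any extra columns.
CORE_COLUMNS = ("subject_id", "condition", "offset")


@dataclass(frozen=True)
class DesignSpec:
    """Target design: total samples and paired-subject fraction.

    Parameters
    ----------
    n_samples_total
        Total number of samples ``N``; must be even and at least 2 so
        the unpaired remainder can be split evenly between arms.
    paired_subject_fraction
        Target proportion ``q`` of subjects contributing paired
        samples, in ``[0, 1]``.
    condition_labels
        Ordered pair of condition names.  The first label is the
        "treatment" level of the TRT contrast (its coefficient is the
        natural-log fold change relative to the second label).
    """

    n_samples_total: int
    paired_subject_fraction: float
    condition_labels: tuple[str, str] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        n = self.n_samples_total
        if not isinstance(n, (int, np.integer)) or n < 2:
            raise ValidationError(f"n_samples_total must be an integer >= 2, got {n!r}")
        if n % 2:
            raise ValidationError(
                f"n_samples_total must be even so unpaired subjects can be "
                f"split evenly between conditions, got {n}"
            )
        q = self.paired_subject_fraction
        if not (0.0 <= q <= 1.0):
            raise ValidationError(f"paired_subject_fraction must lie in [0, 1], got {q}")
        labels = tuple(self.condition_labels)
        if len(labels) != 2 or labels[0] == labels[1]:
            raise ValidationError(
                f"condition_labels must be two distinct labels, got {labels!r}"
            )
        object.__setattr__(self, "condition_labels", labels)

    @property
    def treatment_label(self) -> str:
        return self.condition_labels[0]


class SampleTable:
    """A validated table of samples: one row per expression sample.

    Wraps a :class:`pandas.DataFrame` with the core columns
    ``subject_id``, ``condition`` and ``offset`` (natural log of total
    library size, used as the model offset for count data; 0 for
    continuous designs) plus arbitrary covariate columns.  An optional
    ``sample_id`` column links rows to expression-matrix columns.

    Invariants enforced at construction: every subject appears once
    (unpaired) or exactly twice with distinct conditions (paired), and
    all conditions are drawn from ``condition_labels``.  Pass
    ``require_balanced=True`` to additionally require the unpaired
    subjects to be split evenly between the two arms (true of every
    table built by :func:`build_design`, but not of observational
    cohorts where QC removes samples asymmetrically).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        condition_labels: tuple[str, str] = DEFAULT_CONDITIONS,
        require_balanced: bool = False,
    ) -> None:
        data = data.reset_index(drop=True)
        for col in ("subject_id", "condition"):
            if col not in data.columns:
                raise ValidationError(f"sample table is missing required column {col!r}")
        if "offset" not in data.columns:
            data = data.assign(offset=0.0)
        labels = tuple(condition_labels)
        if len(labels) != 2 or labels[0] == labels[1]:
            raise ValidationError("condition_labels must be two distinct labels")
        bad = set(data["condition"]) - set(labels)
        if bad:
            raise ValidationError(
                f"conditions {sorted(bad)!r} not among condition_labels {labels!r}"
            )
        offs = np.asarray(data["offset"], dtype=float)
        if not np.all(np.isfinite(offs)):
            raise ValidationError("offsets must be finite")
        if np.any(offs < 0):
            raise ValidationError("offsets (log library sizes) must be >= 0")

        counts = data.groupby("subject_id", sort=False)["condition"].agg(["count", "nunique"])
        if (counts["count"] > 2).any():
            bad_subj = counts.index[counts["count"] > 2].tolist()
            raise ValidationError(f"subjects with more than two samples: {bad_subj[:5]}")
        dup = counts.index[(counts["count"] == 2) & (counts["nunique"] == 1)].tolist()
        if dup:
            raise ValidationError(
                f"subjects with two samples under the same condition: {dup[:5]}"
            )
        if "sample_id" in data.columns and data["sample_id"].duplicated().any():
            raise ValidationError("duplicated sample_id values")

        self.data = data
        self.condition_labels = labels

        subj = data["subject_id"]
        n_per = subj.map(subj.value_counts())
        self._paired_mask = (n_per == 2).to_numpy()
        if require_balanced:
            single = data.loc[~self._paired_mask, "condition"]
            n0 = int((single == labels[0]).sum())
            n1 = int((single == labels[1]).sum())
            if n0 != n1:
                raise ValidationError(
                    f"unpaired subjects are not evenly split between conditions "
                    f"({labels[0]}: {n0}, {labels[1]}: {n1})"
                )

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def treatment_label(self) -> str:
        return self.condition_labels[0]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_paired_subjects(self) -> int:
        return int(self._paired_mask.sum()) // 2

    def treatment_indicator(self) -> np.ndarray:
        """0/1 indicator of the treatment condition, one per row."""
        return (self.data["condition"] == self.treatment_label).to_numpy(dtype=float)

    def offsets(self) -> np.ndarray:
        return self.data["offset"].to_numpy(dtype=float)

    def pair_indices(self) -> np.ndarray:
        """(n_pairs, 2) row indices, treatment sample first in each pair."""
        rows: list[tuple[int, int]] = []
        treat = self.treatment_label
        grp = self.data.groupby("subject_id", sort=False).indices
        for subject, idx in grp.items():
            if len(idx) == 2:
                i, j = idx
                if self.data.loc[i, "condition"] != treat:
                    i, j = j, i
                rows.append((int(i), int(j)))
        return np.asarray(rows, dtype=int).reshape(-1, 2)

    def single_indices(self) -> np.ndarray:
        """Row indices of unpaired subjects' samples."""
        return np.flatnonzero(~self._paired_mask)

    def covariate_columns(self) -> list[str]:
        skip = set(CORE_COLUMNS) | {"sample_id"}
        return [c for c in self.data.columns if c not in skip]

    def subset(self, row_indices: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.data.iloc[np.asarray(row_indices)].reset_index(drop=True),
            condition_labels=self.condition_labels,
        )

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, condition_labels: tuple[str, str] | None = None) -> "SampleTable":
        data = pd.read_csv(path, sep="\t", comment="#")
        if condition_labels is None:
            seen = list(dict.fromkeys(data.get("condition", pd.Series(dtype=str))))
            if len(seen) == 1:
                seen = seen + ["__other__"]
            if len(seen) != 2:
                raise ValidationError(
                    f"expected exactly two conditions in file, found {seen!r}"
                )
            condition_labels = (seen[0], seen[1])
        return cls(data, condition_labels=condition_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleTable(n_samples={self.n_samples}, n_subjects={self.n_subjects}, "
            f"n_paired={self.n_paired_subjects}, conditions={self.condition_labels})"
        )


def n_paired_subjects(spec: DesignSpec) -> int:
    """Number of paired subjects P for a design, by half-up rounding.

    ``P = round(q N / (1 + q))`` (half-up), clamped to ``N / 2`` so the
    unpaired remainder is never negative.
    """
    n, q = spec.n_samples_total, spec.paired_subject_fraction
    p = int(math.floor(q * n / (1.0 + q) + 0.5))
    return min(p, n // 2)


def build_design(spec: DesignSpec) -> SampleTable:
    """Construct the sample table realizing a :class:`DesignSpec`.

    Paired subjects contribute one sample per condition; the remaining
    ``U = (N - 2P) / 2`` subjects per arm contribute a single sample.
    Subject ids are generated deterministically (``S0001`` ...) for
    reproducibility.  Offsets are 0 (equal library sizes); simulation
    and generator code may overwrite them.
    """
    p = n_paired_subjects(spec)
    u = (spec.n_samples_total - 2 * p) // 2
    treat, ctrl = spec.condition_labels
    width = max(4, len(str(p + 2 * u)))
    ids = [f"S{i + 1:0{width}d}" for i in range(p + 2 * u)]
    rows: list[tuple[str, str]] = []
    for s in ids[:p]:
        rows.append((s, treat))
        rows.append((s, ctrl))
    for s in ids[p : p + u]:
        rows.append((s, treat))
    for s in ids[p + u :]:
        rows.append((s, ctrl))
    data = pd.DataFrame(rows, columns=["subject_id", "condition"])
    data["offset"] = 0.0
    return SampleTable(data, condition_labels=spec.condition_labels, require_balanced=True)


def realized_fraction(table: SampleTable) -> float:
    """Realized proportion of subjects contributing paired samples."""
    if table.n_subjects == 0:
        raise ValidationError("empty sample table")
    return table.n_paired_subjects / table.n_subjects
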