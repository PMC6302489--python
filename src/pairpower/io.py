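"""Reading and writing expression matrices and sample sheets.

Expression matrices are accepted as tab-delimited gene x sample
tables (first column gene ids, header row of sample ids) or as
MatrixMarket coordinate files with sidecar row/column id lists
(``<file>.rows`` and ``<file>.cols``, one id per line).  Sample
sheets are tab-delimited with the columns described in
:mod:`pairpower.design`.  Output tables carry a provenance header
(comment lines with the package version, the configuration echo and
a config hash); comment lines are skipped on read.  Missing values
are encoded as ``NA``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SampleTable
from .errors import ValidationError


def read_expression(path, counts: bool = False) -> pd.DataFrame:
    """Read a gene x sample expression matrix.

    With ``counts=True`` the values must be nonnegative integers.
    Raises :class:`ValidationError` for duplicated gene or sample ids,
    ragged rows, negative counts, or malformed MatrixMarket input
    (including 0-based indices, which the 1-based standard forbids).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix == ".mtx":
        mat = _read_mtx(path)
    else:
        # pandas silently renames duplicated header fields; check the raw header
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    header = line.rstrip("\n").split("\t")[1:]
                    break
            else:
                raise ValidationError(f"empty expression table {path}")
        if len(header) != len(set(header)):
            dup = sorted({h for h in header if header.count(h) > 1})
            raise ValidationError(f"duplicated sample ids: {dup[:5]}")
        try:
            mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except pd.errors.ParserError as exc:
            raise ValidationError(f"malformed expression table {path}: {exc}") from exc
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()].tolist()
        raise ValidationError(f"duplicated gene ids: {dup[:5]}")
    if mat.columns.duplicated().any():
        dup = mat.columns[mat.columns.duplicated()].tolist()
        raise ValidationError(f"duplicated sample ids: {dup[:5]}")
    values = mat.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix contains non-numeric entries")
    if counts:
        if np.any(values < 0):
            raise ValidationError("negative values in a count matrix")
        if np.any(values != np.floor(values)):
            raise ValidationError("non-integer values in a count matrix")
    mat.index.name = "gene"
    return mat


def _read_mtx(path: Path) -> pd.DataFrame:
    from scipy.io import mmread

    rows_file = path.with_suffix(path.suffix + ".rows")
    cols_file = path.with_suffix(path.suffix + ".cols")
    for f, what in ((rows_file, "row"), (cols_file, "column")):
        if not f.exists():
            raise ValidationError(f"MatrixMarket sidecar {what}-id file missing: {f}")
    # the MatrixMarket coordinate format is 1-based; reject 0-based files
    with open(path) as fh:
        for line in fh:
            if line.startswith("%") or not line.strip():
                continue
            break  # size line
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) >= 2 and (parts[0] == "0" or parts[1] == "0"):
                raise ValidationError(
                    f"{path}: 0-based indices are not valid MatrixMarket "
                    "(the coordinate format is 1-based)"
                )
    try:
        m = mmread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed MatrixMarket file {path}: {exc}") from exc
    dense = np.asarray(m.todense() if hasattr(m, "todense") else m)
    genes = rows_file.read_text().split()
    samples = cols_file.read_text().split()
    if dense.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"matrix shape {dense.shape} does not match id lists "
            f"({len(genes)} rows, {len(samples)} cols)"
        )
    return pd.DataFrame(dense, index=pd.Index(genes, name="gene"), columns=samples)


def read_samples(path, counts: bool = False,
                 condition_labels=None) -> SampleTable:
    """Read and validate a sample sheet.

    Requires ``subject_id`` and ``condition`` columns; ``offset`` is
    required when ``counts=True`` (the count model needs log library
    sizes) and defaults to 0 otherwise.  Pairing invariants are
    validated on load.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    data = pd.read_csv(path, sep="\t", comment="#")
    for col in ("subject_id", "condition"):
        if col not in data.columns:
            raise ValidationError(f"sample sheet {path} is missing column {col!r}")
    if counts and "offset" not in data.columns:
        raise ValidationError(
            f"sample sheet {path} has no 'offset' column; the count family "
            "requires log library-size offsets"
        )
    if condition_labels is None:
        seen = list(dict.fromkeys(data["condition"]))
        if len(seen) != 2:
            raise ValidationError(f"expected exactly two conditions, found {seen!r}")
        condition_labels = tuple(seen)
    return SampleTable(data, condition_labels=condition_labels)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict) -> str:
    from . import __version__

    lines = [f"# pairpower {__version__}", f"# config_hash {config_hash(config)}"]
    for key in sorted(config):
        lines.append(f"# {key} = {config[key]}")
    return "\n".join(lines) + "\n"


def write_table(frame: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a result table as TSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config or {}))
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_expression(matrix: pd.DataFrame, path, mtx: bool = False,
                     config: dict | None = None) -> None:
    """Write a gene x sample matrix as TSV or MatrixMarket + sidecars.

    A provenance header is prepended to TSV output (MatrixMarket's own
    comment syntax does not survive all readers, so ``.mtx`` files are
    written plain).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if mtx:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(matrix.to_numpy()))
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(map(str, matrix.index)) + "\n"
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(map(str, matrix.columns)) + "\n"
        )
    else:
        with open(path, "w") as fh:
            if config is not None:
                fh.write(provenance_header(config))
            matrix.to_csv(fh, sep="\t", na_rep="NA")
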