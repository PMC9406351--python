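"""Expression matrix container and text-format readers/writers.

The canonical on-disk formats are diff-friendly plain text: a probes x samples
TSV for expression values (first column = probe id, header = sample ids) and a
sample-metadata TSV (sample_id, dose_gy, timepoint, replicate).  A GEO
series-matrix reader is provided as an optional convenience for published
two-color array depositions; it is not required by any pipeline stage.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, GroupAbsentError

#: canonical time-point ordering used throughout the pipeline
TIMEPOINT_ORDER = ("2h", "d4", "d7", "d21", "d28")

META_COLUMNS = ("sample_id", "dose_gy", "timepoint", "replicate")


def timepoint_index(tp: str) -> int:
    """Ordinal position of a time-point label in the study time course."""
    try:
        return TIMEPOINT_ORDER.index(tp)
    except ValueError:
        raise DataError(f"unknown timepoint label: {tp!r}") from None


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus per-sample metadata.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns;
    ``meta`` is indexed by sample id with columns dose_gy, timepoint,
    replicate.  Columns of ``values`` and rows of ``meta`` are kept aligned.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicated probe id: {dup!r}")
        if list(self.values.columns) != list(self.meta.index):
            missing = set(self.values.columns) ^ set(self.meta.index)
            raise DataError(
                f"sample ids in matrix and metadata do not match: {sorted(map(str, missing))}"
            )
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")

    # ---- accessors -------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, dose: float, timepoint: str) -> list[str]:
        """Sample ids of one (dose, timepoint) group, in replicate order."""
        m = self.meta
        sel = m[(m["dose_gy"] == dose) & (m["timepoint"] == timepoint)]
        return list(sel.sort_values("replicate").index)

    def group_values(self, dose: float, timepoint: str) -> pd.DataFrame:
        cols = self.group_samples(dose, timepoint)
        if not cols:
            raise GroupAbsentError(
                f"no samples for dose={dose} Gy at timepoint={timepoint!r}"
            )
        return self.values[cols]

    def groups(self) -> list[tuple[float, str]]:
        """All (dose, timepoint) groups present, dose-major, time-ordered."""
        pairs = {
            (float(d), str(t))
            for d, t in zip(self.meta["dose_gy"], self.meta["timepoint"])
        }
        return sorted(pairs, key=lambda p: (p[0], timepoint_index(p[1])))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.meta.loc[sample_ids].copy()
        )


# ---- TSV round-trip ------------------------------------------------------


def write_expression_tsv(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    """Write the probes x samples TSV (and optionally the metadata TSV)."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    if meta_path is not None:
        write_metadata_tsv(matrix.meta, meta_path)


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path, meta_path) -> ExpressionMatrix:
    """Read expression + metadata TSVs into an :class:`ExpressionMatrix`.

    Raises :class:`DataError` naming the offending probe/sample for ragged
    rows, duplicate probe ids, or sample ids present in only one file.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed expression TSV {path}: {exc}") from exc
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise DataError(f"{path}: duplicated probe id {dup!r}")
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise DataError(f"{path}: non-numeric values in column(s) {non_numeric}")
    meta = read_metadata_tsv(meta_path)
    if set(values.columns) != set(meta.index):
        missing = sorted(map(str, set(values.columns) ^ set(meta.index)))
        raise DataError(
            f"sample ids differ between {path} and {meta_path}: {missing}"
        )
    meta = meta.loc[values.columns]
    meta.index.name = "sample_id"  # .loc reindexing drops the name
    return ExpressionMatrix(values, meta)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    want = {"dose_gy", "timepoint", "replicate"}
    if not want <= set(meta.columns):
        raise DataError(f"{path}: metadata must have columns {sorted(want)}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise DataError(f"{path}: duplicated sample id {dup!r}")
    meta["dose_gy"] = meta["dose_gy"].astype(float)
    meta["timepoint"] = meta["timepoint"].astype(str)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


# ---- GEO series-matrix reader (optional convenience) ---------------------


def read_series_matrix(path) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file into an ExpressionMatrix.

    Only the expression table and a minimal set of sample characteristics are
    extracted.  Dose/timepoint are parsed from ``!Sample_characteristics_ch1``
    lines of the form ``dose: 3`` / ``dose_gy: 3`` and ``timepoint: d4``
    (or ``time point: d4``); samples lacking them get NaN dose / empty
    timepoint rather than an error, since depositions vary.
    """
    path = Path(path)
    header_lines: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            (table_lines if in_table else header_lines).append(line)
    if not table_lines:
        raise DataError(f"{path}: no series_matrix table found")
    values = pd.read_csv(
        _io.StringIO("".join(table_lines)), sep="\t", index_col=0
    )
    values.columns = [str(c).strip('"') for c in values.columns]
    values.index = [str(i).strip('"') for i in values.index]
    values = values.dropna(how="all")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise DataError(f"{path}: duplicated probe id {dup!r}")

    dose = {s: np.nan for s in values.columns}
    tp = {s: "" for s in values.columns}
    for line in header_lines:
        if not line.startswith("!Sample_characteristics_ch1"):
            continue
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")[1:]]
        for sample, fieldval in zip(values.columns, fields):
            key, _, val = fieldval.partition(":")
            key = key.strip().lower().replace(" ", "_")
            val = val.strip()
            if key in ("dose", "dose_gy", "dose_(gy)") and val:
                try:
                    dose[sample] = float(val.lower().replace("gy", "").strip())
                except ValueError:
                    pass
            elif key in ("timepoint", "time_point", "time") and val:
                tp[sample] = val
    meta = pd.DataFrame(
        {
            "dose_gy": [dose[s] for s in values.columns],
            "timepoint": [tp[s] for s in values.columns],
            "replicate": range(1, len(values.columns) + 1),
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    vals = values.astype(float)
    if vals.isna().any().any():
        vals = vals.fillna(vals.stack().median())
    return ExpressionMatrix(vals, meta)
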