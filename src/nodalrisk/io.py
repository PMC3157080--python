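"""Reading, validation and subsetting of expression matrices, gene panels and labels.

All files are plain delimited text (tab by default, comma accepted; the
delimiter is auto-detected from the header line). Expression values are
assumed to be already preprocessed and on a log scale — no normalisation or
imputation is applied on read, and missing values are rejected outright: the
signature is small (21 probes) and silent imputation would distort the rank
correlations the predictor depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GenePanel",
    "ReferenceCohort",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_panel",
    "read_labels",
    "subset_to_panel",
]

PRESERVATION_VALUES = ("FFPE", "FF", "unknown")
SPECIMEN_SOURCE_VALUES = ("TUR", "cystectomy", "unknown")


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise FormatError(f"duplicate {what} ID: {ident!r}")
        seen.add(ident)


@dataclass
class ExpressionMatrix:
    """A samples × probes table of log-scale expression intensities.

    Parameters
    ----------
    values
        DataFrame indexed by sample ID with one column per probe ID.
    preservation
        Per-sample tissue preservation, one of ``{"FFPE", "FF", "unknown"}``.
    specimen_source
        Per-sample specimen source, one of ``{"TUR", "cystectomy", "unknown"}``.
    """

    values: pd.DataFrame
    preservation: pd.Series | None = field(default=None)
    specimen_source: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise FormatError("expression matrix is empty")
        _check_unique(self.values.index.astype(str), "sample")
        _check_unique(self.values.columns.astype(str), "probe")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.apply(pd.to_numeric, errors="coerce")
            nn = bad.isna() & self.values.notna()
            if nn.to_numpy().any():
                r, c = np.argwhere(nn.to_numpy())[0]
                raise FormatError(
                    f"non-numeric value at sample {self.values.index[r]!r}, "
                    f"probe {self.values.columns[c]!r}"
                )
            self.values = bad
            arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at sample {self.values.index[r]!r}, "
                f"probe {self.values.columns[c]!r} (missing values are rejected)"
            )
        for name, series, allowed in (
            ("preservation", self.preservation, PRESERVATION_VALUES),
            ("specimen_source", self.specimen_source, SPECIMEN_SOURCE_VALUES),
        ):
            if series is None:
                continue
            series = series.astype(str)
            series.index = series.index.astype(str)
            if not series.index.equals(self.values.index):
                series = series.reindex(self.values.index)
            bad_vals = set(series.dropna()) - set(allowed)
            if bad_vals:
                raise FormatError(f"invalid {name} value(s): {sorted(bad_vals)}")
            series = series.fillna("unknown")
            setattr(self, name, series)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def probe_values(self, probe_id: str) -> pd.Series:
        if probe_id not in self.values.columns:
            raise KeyError(f"probe {probe_id!r} not in matrix")
        return self.values[probe_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class GenePanel:
    """Ordered probe → gene mapping defining a signature.

    The instance used clinically covers 21 probes mapping onto 20 genes,
    but any non-empty mapping with unique probe IDs is accepted.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise FormatError("gene panel is empty")
        _check_unique((p for p, _ in self.entries), "probe")

    @property
    def probe_ids(self) -> list[str]:
        return [p for p, _ in self.entries]

    @property
    def gene_symbols(self) -> list[str]:
        return [g for _, g in self.entries]

    @property
    def n_probes(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return len(set(self.gene_symbols))


@dataclass
class ReferenceCohort:
    """A panel-restricted expression matrix with binary nodal-status labels.

    ``labels`` maps every sample of ``matrix`` to 0 (node-negative) or
    1 (node-positive). This is the neighbor pool the predictor scores
    query profiles against.
    """

    matrix: ExpressionMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        labels = pd.Series(self.labels)
        labels.index = labels.index.astype(str)
        if set(labels.index) != set(self.matrix.sample_ids):
            missing = set(self.matrix.sample_ids) - set(labels.index)
            extra = set(labels.index) - set(self.matrix.sample_ids)
            raise FormatError(
                f"labels do not cover exactly the matrix samples "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        labels = labels.reindex(self.matrix.sample_ids)
        vals = set(labels)
        if not vals <= {0, 1}:
            raise FormatError(f"labels must be 0/1; got {sorted(vals - {0, 1})}")
        self.labels = labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def has_both_classes(self) -> bool:
        return self.labels.nunique() == 2


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression_matrix(
    path: str | Path,
    orientation: Literal["samples-in-rows", "probes-in-rows"] = "samples-in-rows",
) -> ExpressionMatrix:
    """Read a delimited expression matrix and normalise it to samples × probes.

    The first column holds row IDs and the header holds column IDs. With
    ``orientation="probes-in-rows"`` the table is transposed after reading.
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "probes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                # pandas silently mangles duplicate header names; check first
                _check_unique(line.rstrip("\n").split(sep)[1:], "column")
                break
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     float_precision="round_trip")
    if orientation == "probes-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: Literal["samples-in-rows", "probes-in-rows"] = "samples-in-rows",
    sep: str = "\t",
) -> None:
    """Write a matrix as delimited text; values round-trip bit-identically."""
    df = matrix.values if orientation == "samples-in-rows" else matrix.values.T
    df.to_csv(path, sep=sep, index_label="id")


def read_panel(path: str | Path) -> GenePanel:
    """Read a two-column ``probe_id, gene_symbol`` panel file, order preserved."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("panel file must have two columns: probe_id, gene_symbol")
    if df.shape[0] == 0:
        raise FormatError("panel file has no entries")
    entries = tuple(
        (str(p), str(g)) for p, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    )
    return GenePanel(entries=entries)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id, node_status`` file into a 0/1 Series."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("labels file must have two columns: sample_id, node_status")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids, "sample")
    status = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if status.isna().any() or not set(status.dropna()) <= {0, 1}:
        raise FormatError("node_status must be 0 or 1 for every sample")
    return pd.Series(status.astype(int).to_numpy(), index=list(ids), name="node_status")


def subset_to_panel(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    strict: bool = True,
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix's probes to a panel, in panel order.

    Returns the restricted matrix together with the list of panel probes
    missing from the matrix. In strict mode (default) any missing probe is
    an error; in lenient mode missing probes are dropped and reported.
    """
    present = [p for p in panel.probe_ids if p in matrix.values.columns]
    missing = [p for p in panel.probe_ids if p not in matrix.values.columns]
    if missing and strict:
        raise FormatError(f"panel probes missing from matrix: {missing}")
    if not present:
        raise FormatError("no panel probes present in matrix")
    sub = ExpressionMatrix(
        values=matrix.values[present].copy(),
        preservation=matrix.preservation,
        specimen_source=matrix.specimen_source,
    )
    return sub, missing
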