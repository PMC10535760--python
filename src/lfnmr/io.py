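"""Containers and tabular I/O for spectra and bucket tables.

Spectra travel as wide CSV/TSV (one row per sample, ppm values in the
header); bucket tables as CSV with ROI interval labels printed high-ppm
first ("[1.5835–1.4662]"), the convention of NMR tables.  Models and
reports are serialised to JSON by their own modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraCollection",
    "BucketTable",
    "roi_label",
    "parse_roi_label",
    "read_spectra",
    "write_spectra",
    "read_bucket_table",
    "write_bucket_table",
]

_META_COLS = ("sample_id", "group")


class SpectraIOError(ValueError):
    """Raised on malformed spectra/bucket files."""


@dataclass
class SpectraCollection:
    """A set of 1D spectra on one shared, strictly ascending ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise SpectraIOError("ppm axis must be a 1-D vector of length >= 2")
        d = np.diff(self.ppm)
        if np.any(d <= 0):
            raise SpectraIOError("ppm axis must be strictly ascending")
        n, p = self.intensities.shape
        if p != self.ppm.size:
            raise SpectraIOError(
                f"intensity matrix has {p} columns but the axis has {self.ppm.size} points"
            )
        if len(self.sample_ids) != n:
            raise SpectraIOError("one sample id required per spectrum")
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraIOError(f"duplicate sample id(s): {', '.join(dup)}")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraIOError("intensity matrix contains missing/non-finite values")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise SpectraIOError("one group label required per spectrum")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.ppm.size

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.ppm)))

    def copy(self) -> "SpectraCollection":
        return SpectraCollection(
            ppm=self.ppm.copy(),
            intensities=self.intensities.copy(),
            sample_ids=list(self.sample_ids),
            group_labels=None if self.group_labels is None else list(self.group_labels),
        )


def roi_label(interval: tuple[float, float]) -> str:
    """Format an ascending [lo, hi) ppm interval high-ppm first: "[hi–lo]"."""
    lo, hi = interval
    return f"[{hi:.4f}–{lo:.4f}]"


_ROI_RE = re.compile(r"^\[(-?\d+(?:\.\d+)?)–(-?\d+(?:\.\d+)?)\]$")


def parse_roi_label(label: str) -> tuple[float, float]:
    m = _ROI_RE.match(label.strip())
    if m is None:
        raise SpectraIOError(f"not an ROI label: {label!r}")
    hi, lo = float(m.group(1)), float(m.group(2))
    return (lo, hi)


@dataclass
class BucketTable:
    """Samples x features matrix after bucketing (or any feature table).

    ``variables`` holds either ascending (lo, hi) ppm intervals (half-open
    [lo, hi)) or plain string feature ids.  State flags record which
    preprocessing steps produced the values.
    """

    values: np.ndarray
    variables: list
    sample_ids: list[str]
    group_labels: list[str] | None = None
    aligned: bool = False
    normalized: bool = False
    centered: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, p = self.values.shape
        if p < 1 or n < 1:
            raise SpectraIOError("bucket table must be non-empty")
        if len(self.variables) != p:
            raise SpectraIOError("one variable descriptor required per column")
        if len(self.sample_ids) != n:
            raise SpectraIOError("one sample id required per row")
        if len(set(self.sample_ids)) != n:
            raise SpectraIOError("duplicate sample ids in bucket table")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise SpectraIOError("one group label required per row")
        ivals = [v for v in self.variables if isinstance(v, tuple)]
        for lo, hi in ivals:
            if not lo < hi:
                raise SpectraIOError(f"ROI interval ({lo}, {hi}) is not ascending")
        for (a, b), (c, d) in zip(sorted(ivals), sorted(ivals)[1:]):
            if c < b:
                raise SpectraIOError(f"overlapping ROI intervals ({a},{b}) and ({c},{d})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column_labels(self) -> list[str]:
        return [roi_label(v) if isinstance(v, tuple) else str(v) for v in self.variables]

    def copy(self, **updates) -> "BucketTable":
        kw = dict(
            values=self.values.copy(),
            variables=list(self.variables),
            sample_ids=list(self.sample_ids),
            group_labels=None if self.group_labels is None else list(self.group_labels),
            aligned=self.aligned,
            normalized=self.normalized,
            centered=self.centered,
            log_transformed=self.log_transformed,
        )
        kw.update(updates)
        return BucketTable(**kw)


def _frame_to_matrix(df: pd.DataFrame, path) -> tuple[np.ndarray, list[str], list[str] | None, list[str]]:
    if df.columns[0] != "sample_id":
        raise SpectraIOError(f"{path}: first column must be 'sample_id'")
    sample_ids = [str(s) for s in df["sample_id"]]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise SpectraIOError(f"{path}: duplicate sample id(s): {', '.join(dup)}")
    groups = None
    data_cols = list(df.columns[1:])
    if data_cols and data_cols[0] == "group":
        groups = [str(g) for g in df["group"]]
        data_cols = data_cols[1:]
    if not data_cols:
        raise SpectraIOError(f"{path}: no data columns found")
    values = np.empty((len(df), len(data_cols)))
    for j, c in enumerate(data_cols):
        col = df[c]
        try:
            # exact round-trip parsing (pandas' fast path can be off by 1 ulp)
            parsed = np.array([float(v) for v in col], dtype=float)
        except (ValueError, TypeError):
            for i, v in enumerate(col):
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise SpectraIOError(
                        f"{path}: non-numeric value at row {i} "
                        f"(sample {sample_ids[i]}), column {c!r}"
                    ) from None
            raise
        if np.isnan(parsed).any():
            i = int(np.nonzero(np.isnan(parsed))[0][0])
            raise SpectraIOError(
                f"{path}: missing value at row {i} (sample {sample_ids[i]}), column {c!r}"
            )
        values[:, j] = parsed
    return values, sample_ids, groups, data_cols


def read_spectra(path, dialect: str = "wide-csv") -> SpectraCollection:
    """Read a wide spectra file; a descending ppm header is re-sorted
    ascending (vendor exports are typically high-to-low ppm)."""
    if dialect not in ("wide-csv", "wide-tsv"):
        raise SpectraIOError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "wide-csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    values, sample_ids, groups, data_cols = _frame_to_matrix(df, path)
    try:
        ppm = np.array([float(c) for c in data_cols])
    except ValueError as exc:
        raise SpectraIOError(f"{path}: ppm header is not numeric: {exc}") from exc
    order = np.argsort(ppm)
    return SpectraCollection(
        ppm=ppm[order],
        intensities=values[:, order],
        sample_ids=sample_ids,
        group_labels=groups,
    )


def write_spectra(collection: SpectraCollection, path, dialect: str = "wide-csv") -> None:
    if dialect not in ("wide-csv", "wide-tsv"):
        raise SpectraIOError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "wide-csv" else "\t"
    cols = {"sample_id": collection.sample_ids}
    if collection.group_labels is not None:
        cols["group"] = collection.group_labels
    df = pd.DataFrame(cols)
    data = pd.DataFrame(
        collection.intensities, columns=[repr(float(x)) for x in collection.ppm]
    )
    pd.concat([df, data.set_index(df.index)], axis=1).to_csv(path, sep=sep, index=False)


def write_bucket_table(table: BucketTable, path) -> None:
    """CSV with ROI labels formatted "[hi–lo]" at 4 decimals."""
    cols = {"sample_id": table.sample_ids}
    if table.group_labels is not None:
        cols["group"] = table.group_labels
    df = pd.DataFrame(cols)
    data = pd.DataFrame(table.values, columns=table.column_labels())
    pd.concat([df, data.set_index(df.index)], axis=1).to_csv(path, index=False)


def read_bucket_table(path, **flags) -> BucketTable:
    df = pd.read_csv(path, dtype=str)
    values, sample_ids, groups, data_cols = _frame_to_matrix(df, path)
    variables: list = []
    for c in data_cols:
        try:
            variables.append(parse_roi_label(c))
        except SpectraIOError:
            variables.append(c)
    return BucketTable(
        values=values,
        variables=variables,
        sample_ids=sample_ids,
        group_labels=groups,
        **flags,
    )
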