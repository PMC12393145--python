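"""Readers and writers for the pipeline's tabular and geometric formats.

One dialect per kind of artifact: TSV (UTF-8, "." decimal) for tables and
distance matrices, GeoJSON for landscape geometry, JSON for fitted results
and manifests.  Readers validate and reject malformed fields rather than
coercing them; writers emit deterministic column orders so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .kinetics import CELL_COUNT_COLUMNS, SLIDE_TYPES, KineticsError, validate_cell_counts
from .community import CommunityError, validate_count_table

__all__ = [
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_cell_counts",
    "write_cell_counts",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_json",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_count_table(path) -> pd.DataFrame:
    """Read a samples x taxa TSV (first column sample id, integer counts)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header row") from None
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: missing header or taxon columns")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample id(s): {dupes}")
    counts = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        try:
            values = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric count in column {col!r}: {exc}")
        if not np.allclose(values, np.round(values)):
            bad = df.index[values != np.round(values)][0]
            raise FormatError(
                f"{path}: non-integer count at row {bad!r}, column {col!r}"
            )
        counts[col] = values.astype(int)
    return validate_count_table(counts)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table)
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_cell_counts(path) -> pd.DataFrame:
    """Read a cell-count series TSV with the canonical column set."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in CELL_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no records")
    bad = sorted(set(df["slide_type"].unique()) - set(SLIDE_TYPES))
    if bad:
        raise FormatError(
            f"{path}: unknown slide_type {bad}; allowed values: {list(SLIDE_TYPES)}"
        )
    for col in ("offset_m", "day", "cells_per_cm2"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric {col}: {exc}")
    try:
        return validate_cell_counts(df)
    except KineticsError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_cell_counts(series: pd.DataFrame, path) -> None:
    validate_cell_counts(series)
    series.loc[:, list(CELL_COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square TSV with a header row and id column of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column sample ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(c) for c in df.columns])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True) + "\n")
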