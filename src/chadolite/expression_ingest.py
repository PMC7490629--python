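"""Expression assay metadata and per-feature expression values.

The model deliberately collapses the expression module to two tables: an
Assay (name, biomaterial, treatment) and an ExpressionValue per
(feature, assay) cell.  That is exactly what the search facets
("expression biomaterial", "expression treatment") and the feature-page
expression card need.  Values are stored as given (TPM or whatever the
upstream pipeline produced); normalization happens upstream.
"""

from __future__ import annotations

import io

import pandas as pd

from .datastore import (
    DuplicateRecordError,
    FormatError,
    LoadOrderError,
    LoadReport,
    Stopwatch,
    StoreHandle,
)
from .annotation_ingest import _resolve_by_uniquename

__all__ = ["load_assays", "load_expression_matrix"]

_REQUIRED_COLUMNS = ("assay", "biomaterial", "treatment")


def _as_dataframe(stream) -> pd.DataFrame:
    text = stream.read() if hasattr(stream, "read") else str(stream)
    return pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                       keep_default_na=False)


def load_assays(store: StoreHandle, tsv_stream, *,
                on_duplicate: str = "error", progress=None) -> LoadReport:
    """Load assay metadata (TSV with columns assay, biomaterial, treatment)."""
    watch = Stopwatch()
    df = _as_dataframe(tsv_stream)
    for column in _REQUIRED_COLUMNS:
        if column not in df.columns:
            raise FormatError(
                f"assay metadata is missing required column {column!r} "
                f"(found {list(df.columns)})")
    report = LoadReport()
    with store.transaction():
        for _, row in df.iterrows():
            report.records_seen += 1
            name = str(row["assay"]).strip()
            if not name:
                report.add_error(report.records_seen, "empty assay name")
                continue
            existing = store.execute(
                "SELECT assay_id FROM assay WHERE name=?", (name,)).fetchone()
            if existing is not None:
                if on_duplicate == "skip":
                    report.skipped += 1
                    continue
                raise DuplicateRecordError(f"assay {name!r} already loaded")
            store.execute(
                "INSERT INTO assay (name, biomaterial, treatment) VALUES"
                " (?,?,?)", (name, str(row["biomaterial"]),
                             str(row["treatment"])))
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report


def load_expression_matrix(store: StoreHandle, tsv_stream, *,
                           on_duplicate: str = "error",
                           progress=None) -> LoadReport:
    """Load a feature × assay expression matrix.

    The first column holds feature IDs (resolved to mRNAs first); every
    remaining header must name a registered assay, otherwise the load
    aborts with a load-order error pointing at load-assays.  Cells that do
    not parse as numbers, and rows whose feature is unknown, become error
    entries; valid cells each create one expression value.
    """
    watch = Stopwatch()
    df = _as_dataframe(tsv_stream)
    if df.shape[1] < 2:
        raise FormatError("expression matrix needs a feature ID column plus "
                          "at least one assay column")
    assay_names = list(df.columns[1:])
    assay_ids: dict[str, int] = {}
    for name in assay_names:
        row = store.execute("SELECT assay_id FROM assay WHERE name=?",
                            (name,)).fetchone()
        if row is None:
            raise LoadOrderError(
                f"expression matrix names unregistered assay {name!r}",
                "load-assays")
        assay_ids[name] = row[0]

    report = LoadReport()
    report.records_seen = df.shape[0] * len(assay_names)
    with store.transaction():
        for row_no, row in enumerate(df.itertuples(index=False), 1):
            ident = str(row[0])
            feat = _resolve_by_uniquename(
                store, ident, ("mRNA", "gene", "polypeptide"))
            if feat is None:
                report.add_error(row_no, f"unknown feature ID {ident!r}")
                report.skipped += len(assay_names)
                continue
            for col_no, name in enumerate(assay_names, 1):
                raw = row[col_no]
                try:
                    value = float(raw)
                    if value != value:
                        raise ValueError("missing value")
                    if value < 0:
                        raise ValueError("negative expression value")
                except (TypeError, ValueError):
                    report.add_error(
                        row_no, f"non-numeric cell for {ident!r} / {name!r}:"
                        f" {raw!r}")
                    continue
                existing = store.execute(
                    "SELECT 1 FROM expression_value WHERE feature_id=? AND"
                    " assay_id=?", (feat.feature_id, assay_ids[name])
                ).fetchone()
                if existing is not None:
                    if on_duplicate == "skip":
                        report.skipped += 1
                        continue
                    raise DuplicateRecordError(
                        f"expression value for ({ident!r}, {name!r}) "
                        "already loaded")
                store.execute(
                    "INSERT INTO expression_value (feature_id, assay_id,"
                    " value) VALUES (?,?,?)",
                    (feat.feature_id, assay_ids[name], value))
                report.created += 1
            if progress is not None:
                progress(len(assay_names))
    report.elapsed = watch.elapsed()
    return report
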