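"""Readers and writers for %M tables, beta matrices, thresholds and reports.

All artifacts are plain text: CSV/TSV for matrices, JSON for reports and
locked thresholds.  Writers produce files the module's own readers
round-trip without loss, and the threshold file is the structural handle of
the train-lock-test discipline: ``evaluate`` consumes only thresholds that
``lock`` produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .core import (
    CLASS_LABELS,
    MSI_LABELS,
    MSI_UNKNOWN,
    GuardError,
    MethylationMatrix,
    ValidationError,
)
from .clustering import BetaMatrix, Dendrogram
from .roc import LockedThreshold, PerformanceReport
from .selection import SelectionResult

_META_COLUMNS = ("class", "age", "msi")
THRESHOLD_KIND = "methpanel-locked-threshold"


def read_methylation_table(path: str | Path) -> MethylationMatrix:
    """Read a %M table (comma- or tab-delimited, sniffed; CRLF tolerated).

    Expected columns: ``sample_id``, ``class`` (carcinoma/normal), optional
    ``age`` and ``msi`` (MSI/MSS/NA), remaining columns gene %M floats.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # malformed file
        raise ValidationError(f"{path}: cannot parse table: {exc}") from exc
    if "sample_id" not in df.columns or "class" not in df.columns:
        raise ValidationError(f"{path}: header must include sample_id and class")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    bad_class = ~df["class"].isin(CLASS_LABELS)
    if bad_class.any():
        s = df.index[bad_class][0]
        raise ValidationError(
            f"{path}: sample {s!r} has invalid class {df.loc[s, 'class']!r}"
        )
    genes = [c for c in df.columns if c not in _META_COLUMNS]
    if not genes:
        raise ValidationError(f"{path}: no gene columns found")
    values = pd.DataFrame(index=df.index)
    for g in genes:
        col = pd.to_numeric(df[g], errors="coerce")
        newly_bad = col.isna() & df[g].notna()
        if newly_bad.any():
            s = df.index[newly_bad][0]
            raise ValidationError(
                f"{path}: malformed %M at sample {s!r}, gene {g!r}: "
                f"{df.loc[s, g]!r}"
            )
        out_of_range = (col < 0) | (col > 100)
        if out_of_range.any():
            s = df.index[out_of_range][0]
            raise ValidationError(
                f"{path}: %M out of [0, 100] at sample {s!r}, gene {g!r}: "
                f"{col[s]}"
            )
        values[g] = col
    ages = df["age"].astype(float) if "age" in df.columns else None
    msi = None
    if "msi" in df.columns:
        msi = df["msi"].fillna(MSI_UNKNOWN).replace({"NA": MSI_UNKNOWN})
        bad_msi = ~msi.isin(MSI_LABELS)
        if bad_msi.any():
            s = df.index[bad_msi][0]
            raise ValidationError(
                f"{path}: sample {s!r} has invalid msi label {msi[s]!r}"
            )
    return MethylationMatrix(values, df["class"], ages, msi)


def write_methylation_table(
    matrix: MethylationMatrix, path: str | Path, sep: str = ","
) -> None:
    path = Path(path)
    out = matrix.values.copy()
    out.insert(0, "class", matrix.class_labels)
    col = 1
    if matrix.ages is not None:
        out.insert(col, "age", matrix.ages)
        col += 1
    if matrix.msi_labels is not None:
        out.insert(col, "msi", matrix.msi_labels)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def read_beta_matrix(
    matrix_path: str | Path, annotation_path: str | Path
) -> BetaMatrix:
    """Read a probes-x-samples beta TSV plus a (sample_id, class) annotation TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    if "sample_id" not in ann.columns or "class" not in ann.columns:
        raise ValidationError(
            f"{annotation_path}: header must include sample_id and class"
        )
    labels = ann.set_index("sample_id")["class"]
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValidationError(f"annotation missing samples: {missing[:5]}")
    return BetaMatrix(values, labels.reindex(values.columns))


def write_beta_matrix(
    beta: BetaMatrix, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    v = beta.values.copy()
    v.index.name = "probe_id"
    v.to_csv(matrix_path, sep="\t")
    ann = beta.class_labels.rename("class").to_frame()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")


def write_dendrogram(dendrogram: Dendrogram, path: str | Path) -> None:
    """Merge table as TSV: node_a, node_b, height, size."""
    pd.DataFrame(
        dendrogram.merges, columns=["node_a", "node_b", "height", "size"]
    ).to_csv(path, sep="\t", index=False)


# Locked thresholds -----------------------------------------------------------


def save_threshold(locked: LockedThreshold, path: str | Path) -> None:
    payload = {"kind": THRESHOLD_KIND, **asdict(locked)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_threshold(path: str | Path) -> LockedThreshold:
    """Load a threshold file; refuses anything not produced by ``lock``."""
    path = Path(path)
    if not path.exists():
        raise GuardError(
            f"{path}: no locked threshold found — run `lock` on training data first"
        )
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GuardError(f"{path}: not a locked-threshold file: {exc}") from exc
    if payload.pop("kind", None) != THRESHOLD_KIND:
        raise GuardError(f"{path}: not a locked-threshold file")
    return LockedThreshold(**payload)


# Reports ---------------------------------------------------------------------


def save_report(
    report: PerformanceReport, path: str | Path, panel_name: str = "",
    extra: dict | None = None,
) -> None:
    payload = {"panel": panel_name, **report.to_dict(), **(extra or {})}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def save_selection(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "panel": {"name": result.panel.name, "genes": list(result.panel.genes)},
        "shortlist_ranked": list(result.shortlist_ranked),
        "discarded_nonsignificant": list(result.discarded_nonsignificant),
        "discarded_background": list(result.discarded_background),
        "audit": result.audit,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
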