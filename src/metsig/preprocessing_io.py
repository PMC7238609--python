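"""Input/output for fold-change expression data and analysis reports.

The modelling data structure is a samples x genes matrix of log2 fold
changes: each row is one case-control pair, each entry is
``log2(case intensity) - log2(control intensity)`` for one gene.  Matched
controls serve as a per-pair normaliser, so a pair contributes a single row
and is the unit of resampling everywhere downstream.

Files are delimited text (tab or comma, auto-detected) with a header row,
one row per sample, numeric gene columns and a binary outcome column.
Missing values are rejected rather than imputed: the matrix is expected to
be fully pre-processed upstream.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputValidationError",
    "CaseControlPairSet",
    "FoldChangeMatrix",
    "OutcomeVector",
    "compute_log2_fold_change",
    "read_dataset",
    "write_dataset",
    "write_report",
    "read_summary",
]

SAMPLE_ID_COLUMN = "sample_id"


class InputValidationError(ValueError):
    """A dataset or file violates an input contract."""


@dataclass(frozen=True)
class CaseControlPairSet:
    """Paired linear-scale expression intensities for cases and matched controls."""

    pair_ids: tuple[str, ...]
    case_intensity: np.ndarray
    control_intensity: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        case = np.asarray(self.case_intensity, dtype=float)
        ctrl = np.asarray(self.control_intensity, dtype=float)
        object.__setattr__(self, "case_intensity", case)
        object.__setattr__(self, "control_intensity", ctrl)
        if case.shape != ctrl.shape or case.ndim != 2:
            raise InputValidationError(
                f"case and control tables must share one pairs x genes shape; "
                f"got {case.shape} vs {ctrl.shape}"
            )
        if case.shape != (len(self.pair_ids), len(self.gene_ids)):
            raise InputValidationError(
                f"intensity shape {case.shape} does not match "
                f"{len(self.pair_ids)} pairs x {len(self.gene_ids)} genes"
            )
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise InputValidationError("pair_ids must be unique")
        for name, arr in (("case", case), ("control", ctrl)):
            bad = ~(np.isfinite(arr) & (arr > 0))
            if bad.any():
                i, g = np.argwhere(bad)[0]
                raise InputValidationError(
                    f"non-positive or missing {name} intensity at "
                    f"pair {self.pair_ids[i]!r}, gene {self.gene_ids[g]!r}"
                )


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Samples x genes matrix of log2 case-minus-control fold changes."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if vals.ndim != 2 or vals.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise InputValidationError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(vals).all():
            i, g = np.argwhere(~np.isfinite(vals))[0]
            raise InputValidationError(
                f"non-finite fold change at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputValidationError("gene_ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.gene_ids)
        )


@dataclass(frozen=True)
class OutcomeVector:
    """Per-sample binary outcome (1 = metastasis present), aligned with the matrix."""

    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            raise InputValidationError(
                f"outcome must be coded 0/1; found {bad!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.int64))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.sample_ids) != len(vals):
            raise InputValidationError("outcome length does not match sample_ids")

    @property
    def n(self) -> int:
        return len(self.values)

    def require_both_classes(self, minimum: int = 2) -> None:
        pos = int(self.values.sum())
        neg = self.n - pos
        if pos < minimum or neg < minimum:
            raise InputValidationError(
                f"need at least {minimum} samples of each class; "
                f"got {pos} positives and {neg} negatives"
            )


def compute_log2_fold_change(pairs: CaseControlPairSet) -> FoldChangeMatrix:
    """Build the log2 fold-change matrix log2(case) - log2(control).

    Entry (i, g) is ``log2(case_intensity[i, g]) - log2(control_intensity[i, g])``,
    so swapping the case and control tables negates every entry.
    """
    values = np.log2(pairs.case_intensity) - np.log2(pairs.control_intensity)
    return FoldChangeMatrix(values, pairs.pair_ids, pairs.gene_ids)


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset(
    path: str, outcome_column: str = "metastasis"
) -> tuple[FoldChangeMatrix, OutcomeVector]:
    """Read an aligned fold-change matrix and outcome from a delimited text file.

    The file needs a header row and one row per sample.  An optional
    ``sample_id`` column supplies identifiers; every other non-outcome column
    is a gene.  Gene order from the file is preserved.
    """
    sep = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    for name in header:
        if name in seen:  # pandas would silently mangle these to g, g.1, ...
            raise InputValidationError(f"{path}: duplicate gene column {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, dtype={SAMPLE_ID_COLUMN: str})
    if outcome_column not in df.columns:
        raise InputValidationError(
            f"{path}: outcome column {outcome_column!r} not found"
        )
    if SAMPLE_ID_COLUMN in df.columns:
        sample_ids = [str(s) for s in df.pop(SAMPLE_ID_COLUMN)]
    else:
        sample_ids = [f"sample{i}" for i in range(len(df))]

    outcome_raw = df.pop(outcome_column)
    if outcome_raw.isna().any():
        row = int(outcome_raw.isna().idxmax())
        raise InputValidationError(f"{path}: missing outcome in data row {row}")
    if not np.isin(outcome_raw.to_numpy(), (0, 1)).all():
        bad = outcome_raw[~outcome_raw.isin((0, 1))]
        raise InputValidationError(
            f"{path}: outcome column {outcome_column!r} must be 0/1; "
            f"found {bad.iloc[0]!r} in data row {int(bad.index[0])}"
        )

    gene_ids = [str(c) for c in df.columns]
    dupes = df.columns[df.columns.duplicated()]
    if len(dupes):
        raise InputValidationError(f"{path}: duplicate gene column {dupes[0]!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise InputValidationError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in gene column "
                f"{col!r}, data row {int(bad.index[0])}"
            )
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise InputValidationError(
                f"{path}: missing value in gene column {col!r}, data row {row}"
            )

    X = FoldChangeMatrix(df.to_numpy(dtype=float), sample_ids, gene_ids)
    y = OutcomeVector(outcome_raw.to_numpy(), sample_ids)
    return X, y


def write_dataset(
    X: FoldChangeMatrix,
    y: OutcomeVector,
    path: str,
    outcome_column: str = "metastasis",
    sep: str = "\t",
) -> None:
    """Write matrix + outcome to delimited text, round-trippable by read_dataset."""
    if X.sample_ids != y.sample_ids:
        raise InputValidationError("matrix and outcome sample_ids differ")
    df = X.to_frame()
    df.insert(0, SAMPLE_ID_COLUMN, list(X.sample_ids))
    df[outcome_column] = y.values
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Report serialization


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_report(report, outdir: str) -> list[str]:
    """Write a ValidationReport or StabilityReport as delimited tables + JSON.

    Output is deterministic given an identical report.  Returns the list of
    files written.  Dispatches on report type (duck-typed on fields so the
    bootstrap module does not need to be imported here).
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    if hasattr(report, "selection_probability"):
        written += _write_stability(report, outdir)
    elif hasattr(report, "brier"):
        written += _write_validation(report, outdir)
    else:
        raise TypeError(f"unrecognized report type {type(report).__name__}")
    return written


def _write_validation(rep, outdir: str) -> list[str]:
    files = []

    path = os.path.join(outdir, "metric_summary.tsv")
    rows = []
    for name in ("brier", "concordance"):
        m = getattr(rep, name)
        rows.append(
            {
                "metric": name,
                "apparent": m.apparent,
                "mean_optimism": m.mean_optimism,
                "corrected": m.corrected,
                "lower80": m.interval80[0],
                "upper80": m.interval80[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)

    path = os.path.join(outdir, "calibration_curve.tsv")
    cal = rep.calibration
    pd.DataFrame(
        {
            "predicted": cal.grid,
            "observed_apparent": cal.apparent,
            "observed_corrected": cal.corrected,
            "lower80": cal.band_lower,
            "upper80": cal.band_upper,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)

    path = os.path.join(outdir, "bootstrap_distributions.tsv")
    pd.DataFrame(
        {
            "replicate": np.arange(len(rep.brier.replicate_corrected)),
            "brier_corrected": rep.brier.replicate_corrected,
            "concordance_corrected": rep.concordance.replicate_corrected,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)

    path = os.path.join(outdir, "validation_summary.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(rep), fh, indent=1, sort_keys=True)
        fh.write("\n")
    files.append(path)
    return files


def _write_stability(rep, outdir: str) -> list[str]:
    files = []

    path = os.path.join(outdir, "gene_table.tsv")
    probs = rep.selection_probability
    # Descending probability, gene id breaking ties, mirroring the usual
    # "selected genes ordered by selection probability" table.
    order = sorted(probs, key=lambda g: (-probs[g], g))
    pd.DataFrame(
        {"gene_id": order, "selection_probability": [probs[g] for g in order]}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)

    path = os.path.join(outdir, "co_selection.tsv")
    pairs = sorted(rep.co_selection)
    pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "co_selection_probability": [rep.co_selection[p] for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)

    path = os.path.join(outdir, "jaccard_values.tsv")
    pd.DataFrame({"jaccard": rep.jaccard_values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    files.append(path)

    path = os.path.join(outdir, "stability_summary.json")
    payload = _jsonable(rep)
    payload["co_selection"] = {f"{a}\t{b}": v for (a, b), v in rep.co_selection.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files.append(path)
    return files


def read_summary(path: str) -> dict:
    """Read back a JSON summary written by write_report."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
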