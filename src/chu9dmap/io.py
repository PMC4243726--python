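"""Delimited-text I/O for respondent records, predictions and Rasch tables.

CSV dialect: comma-delimited (configurable), UTF-8, header mandatory.
Recognised columns: ``ks_i1``..``ks_i10``, ``ks_index``, ``age``,
``gender``, ``chu9d``.  Ingest is complete-case and strict by default:
malformed rows raise with their line numbers; ``on_error="drop"`` keeps
valid rows and reports the rejects instead.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .instruments import (ITEM_LABELS, VALUE_SETS, PairedDataset,
                          RaschLookupTable, ResponseValidationError,
                          validate_responses)
from .mapping import BatchPrediction

logger = logging.getLogger("chu9dmap")


class IngestError(ValueError):
    """Row-level validation failures, with line numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:5])
        more = f" (+{len(problems) - 5} more)" if len(problems) > 5 else ""
        super().__init__(f"{len(problems)} invalid row(s): {preview}{more}")


def read_paired_csv(path, delimiter: str = ",",
                    reverse_coded: Iterable[str] = (),
                    value_set: str = "AU_adolescent_BWS",
                    on_error: str = "raise") -> PairedDataset:
    """Read respondent records; returns a :class:`PairedDataset`.

    Requires the ten item columns; ``ks_index``, ``age``, ``gender`` and
    ``chu9d`` are picked up when present.  Observed ``chu9d`` values must
    lie within the value set's [floor, 1] range.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in ITEM_LABELS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    floor = VALUE_SETS[value_set]["floor"]
    problems, keep, items = [], [], []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2                     # header is line 1
        try:
            vec = validate_responses(dict(row), reverse_coded=reverse_coded)
            if "chu9d" in df.columns:
                u = row["chu9d"]
                if pd.isna(u):
                    raise ResponseValidationError("chu9d: missing value")
                if not floor <= float(u) <= 1.0:
                    raise ResponseValidationError(
                        f"chu9d: observed utility {u} outside [{floor}, 1]")
            for c in ("ks_index", "age", "gender"):
                if c in df.columns and pd.isna(row[c]):
                    raise ResponseValidationError(f"{c}: missing value")
        except (ResponseValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        keep.append(pos)
        items.append(vec.levels)
    if problems:
        if on_error == "raise":
            raise IngestError(problems)
        for msg in problems:
            logger.warning("rejected %s", msg)
    logger.info("read %d record(s), rejected %d", len(keep), len(problems))
    if not keep:
        logger.warning("no valid records in %s", path)
        return PairedDataset(items=np.empty((0, 10), dtype=int),
                             value_set=value_set, provenance=str(path))
    sub = df.iloc[keep]
    col = lambda c, dtype=float: (sub[c].to_numpy(dtype=dtype)
                                  if c in df.columns else None)
    return PairedDataset(
        items=np.asarray(items, dtype=int),
        utility=col("chu9d"), index=col("ks_index"),
        age=col("age"), gender=col("gender"),
        value_set=value_set, provenance=str(path))


def write_paired_csv(path, data: PairedDataset, delimiter: str = ",",
                     precision: int = 6) -> None:
    df = data.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False,
              float_format=f"%.{precision}f")


def write_predictions_csv(path, batch: BatchPrediction,
                          delimiter: str = ",", precision: int = 6) -> None:
    """Write per-record raw and truncated predictions."""
    df = pd.DataFrame({
        "prediction_raw": batch.raw,
        "prediction_truncated": batch.truncated,
    })
    df.to_csv(path, sep=delimiter, index=False,
              float_format=f"%.{precision}f")


def load_rasch_table(path, t_slope: float = 1.0, t_intercept: float = 0.0,
                     delimiter: str = ",") -> RaschLookupTable:
    """Two-column CSV (sum, person_parameter) plus transform constants."""
    df = pd.read_csv(path, delimiter=delimiter)
    if df.shape[1] < 2:
        raise ValueError("Rasch table needs two columns: sum, person_parameter")
    mapping = {int(s): float(p) for s, p in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return RaschLookupTable(mapping, t_slope=t_slope, t_intercept=t_intercept)
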