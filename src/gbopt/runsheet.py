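"""Run-sheet CSV I/O and the packaged 49-run reference dataset.

A run sheet is a UTF-8 comma-separated file with header
``run_id,temperature_C,geniposide,glycine,time_min[,yield_ugml]``; the yield
column is optional on read (a design awaiting measurement) and written
whenever responses are present.

The packaged dataset ``data/oa49_yields.csv`` is the 49-run mixed-level
orthogonal experiment of one-step enzymatic gardenia-blue production
(yields in μg/mL) that the surrogate and optimizer modules are demonstrated
on throughout the documentation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    RUN_SHEET_COLUMNS,
    YIELD_COLUMN,
    DesignError,
    DesignTable,
    FactorSpec,
    REFERENCE_FACTORS,
)


class RunSheetError(ValueError):
    """Malformed run-sheet file (schema, parse or emptiness problems)."""


def _frame_to_design(
    frame: pd.DataFrame, factors: tuple[FactorSpec, ...]
) -> tuple[DesignTable, np.ndarray | None]:
    value_cols = list(RUN_SHEET_COLUMNS[1:])
    idx = np.empty((len(frame), len(factors)), dtype=int)
    for f, (spec, col) in enumerate(zip(factors, value_cols)):
        for r, v in enumerate(frame[col].to_numpy()):
            try:
                idx[r, f] = spec.index_of(float(v))
            except DesignError as exc:
                raise RunSheetError(
                    f"row run_id={frame['run_id'].iloc[r]}: {exc}"
                ) from exc
    design = DesignTable(
        factors=factors,
        level_index=idx,
        run_id=frame["run_id"].to_numpy(dtype=int),
    )
    yields = None
    if YIELD_COLUMN in frame.columns:
        yields = frame[YIELD_COLUMN].to_numpy(dtype=float)
    return design, yields


def load_run_sheet(
    path: str | Path, factors: tuple[FactorSpec, ...] = REFERENCE_FACTORS
) -> tuple[DesignTable, np.ndarray | None]:
    """Read and validate a run-sheet CSV; returns (design, yields-or-None)."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RunSheetError(f"{path}: file is empty") from exc
    missing = [c for c in RUN_SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise RunSheetError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise RunSheetError(f"{path}: header only, no runs")
    for col in list(RUN_SHEET_COLUMNS) + (
        [YIELD_COLUMN] if YIELD_COLUMN in frame.columns else []
    ):
        bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise RunSheetError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row run_id={bad.iloc[0]['run_id']!r}"
            )
    return _frame_to_design(frame, factors)


def save_run_sheet(
    path: str | Path, design: DesignTable, yields: np.ndarray | None = None
) -> None:
    """Write a run sheet with the canonical header (yield column if given)."""
    design.to_frame(yields).to_csv(path, index=False)


def load_reference_dataset() -> tuple[DesignTable, np.ndarray]:
    """The packaged 49-run orthogonal experiment with measured yields."""
    source = resources.files("gbopt.data").joinpath("oa49_yields.csv")
    with resources.as_file(source) as path:
        design, yields = load_run_sheet(path)
    assert yields is not None
    return design, yields
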