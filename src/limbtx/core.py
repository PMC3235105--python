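"""Shared constants, exceptions and sample-sheet helpers.

The study design is a five-point embryonic time course (E9.5–E13.5) with
three tissues per stage: forelimb, hindlimb and a whole-embryo control.
Hindlimb development lags the forelimb by roughly half a day, so hindlimb
sampling starts one stage later (no hindlimb at E9.5).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

#: Canonical stage order of the time course.
STAGES: tuple[str, ...] = ("E9.5", "E10.5", "E11.5", "E12.5", "E13.5")

FORELIMB = "forelimb"
HINDLIMB = "hindlimb"
WHOLE_EMBRYO = "whole_embryo"
TISSUES: tuple[str, ...] = (FORELIMB, HINDLIMB, WHOLE_EMBRYO)

#: Columns every sample sheet must carry.
SHEET_COLUMNS = ("array_id", "tissue", "stage", "replicate")


class LimbtxError(Exception):
    """Base class for all package errors."""


class ConfigError(LimbtxError, ValueError):
    """Invalid configuration or parameter value."""


class DataError(LimbtxError, ValueError):
    """Inconsistent or malformed input data."""


def stage_index(stage: str, stages: Sequence[str] = STAGES) -> int:
    try:
        return list(stages).index(stage)
    except ValueError:
        raise DataError(f"unknown stage {stage!r}; expected one of {list(stages)}") from None


def validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet for required columns, known labels and unique ids."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise DataError(f"sample sheet is missing columns {missing}")
    if sheet["array_id"].duplicated().any():
        dups = sheet.loc[sheet["array_id"].duplicated(), "array_id"].tolist()
        raise DataError(f"duplicate array ids in sample sheet: {dups}")
    bad_tissue = set(sheet["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise DataError(f"unknown tissue labels {sorted(bad_tissue)}")
    bad_stage = set(sheet["stage"]) - set(STAGES)
    if bad_stage:
        raise DataError(f"unknown stage labels {sorted(bad_stage)}")
    return sheet


def group_arrays(sheet: pd.DataFrame, tissue: str, stage: str) -> list[str]:
    """Array ids belonging to one (tissue, stage) replicate group."""
    mask = (sheet["tissue"] == tissue) & (sheet["stage"] == stage)
    return sheet.loc[mask, "array_id"].tolist()


def limb_arrays(sheet: pd.DataFrame, stages: Iterable[str] | None = None) -> list[str]:
    """All fore- and hind-limb array ids, optionally restricted to stages."""
    mask = sheet["tissue"].isin((FORELIMB, HINDLIMB))
    if stages is not None:
        mask &= sheet["stage"].isin(list(stages))
    return sheet.loc[mask, "array_id"].tolist()
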