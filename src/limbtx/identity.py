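"""Fore- vs hindlimb identity calling with the developmental-delay adjustment.

Hindlimb development lags the forelimb by roughly half a day — one stage in
this sampling grid. A gene up-regulated in the forelimb at a stage might
therefore show up in the hindlimb one stage later without being
forelimb-specific. The delay rule vetoes such genes:

* forelimb-specific at stage s: up in FL-vs-control at s, AND not up in
  HL-vs-control at s, AND not up in HL-vs-control at s+1;
* hindlimb-specific at stage s: up in HL-vs-control at s, AND not up in
  FL-vs-control at s, AND not up in FL-vs-control at s-1.

Boundary stages use whichever vetoes exist: at E9.5 there is no hindlimb
sample, so forelimb specificity there rests on the E10.5 hindlimb veto
alone; at E13.5 no later stage exists. "Not up" means the call is down or
unchanged. The direct forelimb-vs-hindlimb moderated-t contrast
(``interlimb_de``) complements the set logic with a quantitative
within-stage comparison.
"""

from __future__ import annotations

import pandas as pd

from .core import FORELIMB, HINDLIMB, STAGES, DataError, stage_index
from .de import Contrast, ModerationParams, run_contrasts


def _calls(de: pd.DataFrame, contrast: str) -> pd.Series | None:
    sub = de[de["contrast"] == contrast]
    if sub.empty:
        return None
    return sub.set_index("gene")["call"]


def _up_set(calls: pd.Series | None) -> set[str] | None:
    return None if calls is None else set(calls.index[calls == "up"])


def forelimb_specific(de: pd.DataFrame, stage: str) -> set[str]:
    """Forelimb-specific genes at one stage under the delay rule."""
    idx = stage_index(stage)
    up_fl = _up_set(_calls(de, f"FL_vs_WE@{stage}"))
    if up_fl is None:
        raise DataError(f"DE table lacks contrast FL_vs_WE@{stage}")
    vetoes = [up for up in (
        _up_set(_calls(de, f"HL_vs_WE@{stage}")),
        _up_set(_calls(de, f"HL_vs_WE@{STAGES[idx + 1]}")) if idx + 1 < len(STAGES) else None,
    ) if up is not None]
    result = set(up_fl)
    for veto in vetoes:
        result -= veto
    return result


def hindlimb_specific(de: pd.DataFrame, stage: str) -> set[str]:
    """Hindlimb-specific genes at one stage under the delay rule."""
    idx = stage_index(stage)
    if idx == 0:
        raise DataError(f"no hindlimb data at {stage} by design")
    up_hl = _up_set(_calls(de, f"HL_vs_WE@{stage}"))
    if up_hl is None:
        raise DataError(f"DE table lacks contrast HL_vs_WE@{stage}")
    vetoes = [up for up in (
        _up_set(_calls(de, f"FL_vs_WE@{stage}")),
        _up_set(_calls(de, f"FL_vs_WE@{STAGES[idx - 1]}")),
    ) if up is not None]
    result = set(up_hl)
    for veto in vetoes:
        result -= veto
    return result


def identity_table(de: pd.DataFrame) -> pd.DataFrame:
    """All identity calls across stages, with the underlying evidence.

    One row per (gene, side, stage) with the three call states that
    support it (the same-stage call for the claimed side and the two veto
    calls, "absent" where no contrast exists).
    """
    rows = []
    contrasts = set(de["contrast"])
    call_lookup = {c: _calls(de, c) for c in contrasts}

    def evidence(contrast: str, gene: str) -> str:
        series = call_lookup.get(contrast)
        if series is None or gene not in series.index:
            return "absent"
        return series[gene]

    for stage in STAGES:
        idx = stage_index(stage)
        if f"FL_vs_WE@{stage}" in contrasts:
            next_stage = STAGES[idx + 1] if idx + 1 < len(STAGES) else None
            for gene in sorted(forelimb_specific(de, stage)):
                rows.append({
                    "gene": gene, "side": FORELIMB, "stage": stage,
                    "own_call": evidence(f"FL_vs_WE@{stage}", gene),
                    "other_same_stage": evidence(f"HL_vs_WE@{stage}", gene),
                    "other_delay_stage": (evidence(f"HL_vs_WE@{next_stage}", gene)
                                          if next_stage else "absent"),
                })
        if idx > 0 and f"HL_vs_WE@{stage}" in contrasts:
            prev_stage = STAGES[idx - 1]
            for gene in sorted(hindlimb_specific(de, stage)):
                rows.append({
                    "gene": gene, "side": HINDLIMB, "stage": stage,
                    "own_call": evidence(f"HL_vs_WE@{stage}", gene),
                    "other_same_stage": evidence(f"FL_vs_WE@{stage}", gene),
                    "other_delay_stage": evidence(f"FL_vs_WE@{prev_stage}", gene),
                })
    return pd.DataFrame(rows, columns=["gene", "side", "stage", "own_call",
                                       "other_same_stage", "other_delay_stage"])


def interlimb_de(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    stage: str,
    *,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Direct forelimb-vs-hindlimb moderated-t contrast at one stage.

    Adds a ``side`` column: genes at fc >= fc_threshold (and significant)
    are forelimb-enriched, fc <= 1/fc_threshold hindlimb-enriched.
    """
    contrast = Contrast(f"FL_vs_HL@{stage}", FORELIMB, stage, HINDLIMB, stage)
    try:
        de = run_contrasts(matrix, sheet, [contrast],
                           fc_threshold=fc_threshold, p_threshold=p_threshold,
                           params=params)
    except DataError as err:
        raise DataError(f"interlimb contrast at {stage} not possible: {err}") from err
    de = de.copy()
    de["side"] = de["call"].map({"up": FORELIMB, "down": HINDLIMB, "unchanged": "none"})
    return de


def write_identity(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
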