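"""Combinatorial temporal expression-profile classification.

Per-stage DE calls against the whole-embryo control are binarized
(up-regulated vs down-regulated/unchanged) into an ordered 5-tuple over
E9.5–E13.5. The 31 non-empty tuples are the profile classes — every
possible combination of stages at which a gene can be up. Classes fall
into five categories:

* stage-specific — up at exactly one stage (5 classes);
* early — one contiguous run starting at E9.5, >=2 stages (4 classes);
* late — one contiguous run ending at E13.5, not starting at E9.5 (3);
* peak — one contiguous internal run touching neither end (3);
* oscillating — the up stages are not contiguous (16).

The class id of a pattern is the value of its bitstring with E9.5 as the
most significant bit (1–31), a fixed bijection with the non-empty tuples.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .core import STAGES, DataError, stage_index

Pattern = tuple[bool, ...]

N_STAGES = len(STAGES)

CATEGORIES = ("stage-specific", "early", "late", "peak", "oscillating")


def class_id(pattern: Pattern) -> int:
    """Bitstring value of the pattern, E9.5 as the most significant bit."""
    if len(pattern) != N_STAGES:
        raise DataError(f"pattern must have {N_STAGES} entries, got {len(pattern)}")
    value = 0
    for bit in pattern:
        value = (value << 1) | int(bool(bit))
    if value == 0:
        raise DataError("the empty pattern has no class id")
    return value


def pattern_from_id(cid: int) -> Pattern:
    if not 1 <= cid <= 2 ** N_STAGES - 1:
        raise DataError(f"class id must be in 1..{2 ** N_STAGES - 1}, got {cid}")
    return tuple(bool((cid >> (N_STAGES - 1 - i)) & 1) for i in range(N_STAGES))


def pattern_to_string(pattern: Pattern) -> str:
    return "".join("1" if b else "0" for b in pattern)


def pattern_from_string(bits: str) -> Pattern:
    if len(bits) != N_STAGES or set(bits) - {"0", "1"}:
        raise DataError(f"pattern string must be {N_STAGES} characters of 0/1, got {bits!r}")
    return tuple(b == "1" for b in bits)


#: All 31 non-empty patterns in class-id order.
ALL_PATTERNS: tuple[Pattern, ...] = tuple(
    pattern_from_id(cid) for cid in range(1, 2 ** N_STAGES)
)


def pattern_of(calls) -> Pattern:
    """Binarize one call per stage: up → True; down/unchanged → False."""
    calls = list(calls)
    if len(calls) != N_STAGES:
        raise DataError(f"expected {N_STAGES} calls (one per stage), got {len(calls)}")
    bad = set(calls) - {"up", "down", "unchanged"}
    if bad:
        raise DataError(f"unknown call values {sorted(bad)}")
    return tuple(c == "up" for c in calls)


def categorize(pattern: Pattern) -> str:
    """Assign one of the five temporal categories to a non-empty pattern."""
    up = [i for i, b in enumerate(pattern) if b]
    if len(pattern) != N_STAGES:
        raise DataError(f"pattern must have {N_STAGES} entries")
    if not up:
        raise DataError("cannot categorize the empty pattern")
    if len(up) == 1:
        return "stage-specific"
    if up != list(range(up[0], up[-1] + 1)):
        return "oscillating"
    if up[0] == 0:
        return "early"
    if up[-1] == N_STAGES - 1:
        return "late"
    return "peak"


def class_census() -> dict[str, int]:
    """Count of the 31 classes per category (a fixed partition: 5/4/3/3/16)."""
    census = {cat: 0 for cat in CATEGORIES}
    for pattern in ALL_PATTERNS:
        census[categorize(pattern)] += 1
    return census


def assign_profiles(de: pd.DataFrame, *, tissue_prefix: str = "FL_vs_WE") -> pd.DataFrame:
    """Profile assignments from a DE table's per-stage limb-vs-control calls.

    Uses the ``{tissue_prefix}@{stage}`` contrasts for all five stages.
    Genes up-regulated at no stage are excluded (the empty pattern is not a
    class). Returns a frame indexed by gene with columns pattern (bitstring),
    class_id and category.
    """
    contrasts = [f"{tissue_prefix}@{stage}" for stage in STAGES]
    missing = set(contrasts) - set(de["contrast"].unique())
    if missing:
        raise DataError(f"DE table lacks contrasts {sorted(missing)}")
    sub = de[de["contrast"].isin(contrasts)]
    calls = sub.pivot(index="gene", columns="contrast", values="call")[contrasts]
    up = (calls == "up").to_numpy()
    patterns = [tuple(row) for row in up]
    keep = [any(p) for p in patterns]
    genes = calls.index[keep]
    kept_patterns = list(itertools.compress(patterns, keep))
    return pd.DataFrame(
        {
            "pattern": [pattern_to_string(p) for p in kept_patterns],
            "class_id": [class_id(p) for p in kept_patterns],
            "category": [categorize(p) for p in kept_patterns],
        },
        index=pd.Index(genes, name="gene"),
    )


def stage_specific(assignments: pd.DataFrame, stage: str) -> set[str]:
    """Genes up-regulated at exactly the given stage and nowhere else."""
    idx = stage_index(stage)
    target = pattern_to_string(tuple(i == idx for i in range(N_STAGES)))
    return set(assignments.index[assignments["pattern"] == target])


def exclusive_between_consecutive(
    de: pd.DataFrame, stage_a: str, stage_b: str, *, tissue_prefix: str = "FL_vs_WE"
) -> tuple[set[str], set[str]]:
    """Genes up at one of two consecutive stages but not the other.

    Returns (up at stage_a only, up at stage_b only); down and unchanged
    both count as "not up".
    """
    if stage_index(stage_b) != stage_index(stage_a) + 1:
        raise DataError(f"{stage_a} and {stage_b} are not consecutive stages")
    ups = {}
    for stage in (stage_a, stage_b):
        name = f"{tissue_prefix}@{stage}"
        sub = de[de["contrast"] == name]
        if sub.empty:
            raise DataError(f"DE table lacks contrast {name}")
        ups[stage] = set(sub.loc[sub["call"] == "up", "gene"])
    return ups[stage_a] - ups[stage_b], ups[stage_b] - ups[stage_a]


def top_upregulated(de: pd.DataFrame, contrast: str, n: int) -> pd.DataFrame:
    """The n genes passing the DE call, sorted by fold change descending.

    Ties break by adjusted p ascending, then gene id, so the ranking is
    deterministic. Returns fewer than n rows if fewer genes qualify.
    """
    if n <= 0:
        raise DataError(f"n must be positive, got {n}")
    sub = de[de["contrast"] == contrast]
    if sub.empty:
        raise DataError(f"DE table lacks contrast {contrast}")
    hits = sub[sub["call"] == "up"]
    ranked = hits.sort_values(
        ["fc", "adj_p", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)
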