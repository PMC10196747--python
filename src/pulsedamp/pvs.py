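"""Ordinal scoring of MRI-visible perivascular spaces (PVS).

PVS are counted on the single highest-burden slice of one hemisphere in
two regions — basal ganglia (BG) and centrum semiovale (CSO) — and
stratified into a 4-level score:

    0: <= 10 PVS    1: 11-25    2: 26-40    3: >= 41

Sparsely populated extreme levels are merged region-specifically before
statistical analysis (BG: 3 -> 2; CSO: 0 -> 1), a power decision exposed
here as a configurable mapping.  Frequencies are reported on the raw
scale; analyses consume the merged score.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = ["PVSScore", "count_to_score", "score_frequencies", "DEFAULT_MERGE", "score_cohort"]

BIN_EDGES = (10, 25, 40)  # raw level k iff count <= edge_k, else 3

# region -> {raw level: merged level}; identity where omitted
DEFAULT_MERGE: dict[str, dict[int, int]] = {"BG": {3: 2}, "CSO": {0: 1}}

_REGIONS = ("BG", "CSO")


@dataclass(frozen=True)
class PVSScore:
    region: str
    raw_score: int
    merged_score: int


def count_to_score(
    count: int, region: str, merge: dict[str, dict[int, int]] | None = None
) -> PVSScore:
    """Map a PVS count to its raw and merged ordinal score.

    Raw bins: 0 for counts 0-10, 1 for 11-25, 2 for 26-40, 3 for >= 41.
    The merge table (default ``DEFAULT_MERGE``) then collapses sparse
    levels per region.
    """
    region = region.upper()
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}")
    if isinstance(count, bool) or int(count) != count:
        raise ValueError("count must be an integer")
    count = int(count)
    if count < 0:
        raise ValueError("count must be non-negative")
    raw = sum(count > edge for edge in BIN_EDGES)
    merge = DEFAULT_MERGE if merge is None else merge
    merged = merge.get(region, {}).get(raw, raw)
    return PVSScore(region=region, raw_score=raw, merged_score=merged)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))


def score_frequencies(scores) -> pd.DataFrame:
    """Frequency table of ordinal scores: level -> (count, percent).

    Percentages are 100 * count / n rounded half-up to one decimal, the
    convention of descriptive cohort tables.  Levels 0-3 are always
    listed, including empty ones.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    n = len(scores)
    rows = []
    for level in range(4):
        k = sum(s == level for s in scores)
        rows.append({"level": level, "count": k, "percent": _round_half_up(100.0 * k / n)})
    return pd.DataFrame(rows).set_index("level")


def score_cohort(
    table: pd.DataFrame, merge: dict[str, dict[int, int]] | None = None
) -> pd.DataFrame:
    """Add merged ``pvs_bg_score`` / ``pvs_cso_score`` columns from the
    ``pvs_bg_count`` / ``pvs_cso_count`` columns of a cohort table."""
    out = table.copy()
    out["pvs_bg_score"] = [
        count_to_score(c, "BG", merge).merged_score for c in table["pvs_bg_count"]
    ]
    out["pvs_cso_score"] = [
        count_to_score(c, "CSO", merge).merged_score for c in table["pvs_cso_count"]
    ]
    return out
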