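"""Absolute-abundance ranking from iBAQ intensities and the housekeeping proteome.

iBAQ (intensity-based absolute quantification) is a proxy for protein copy
number; ranking the global median iBAQ of a deep proteome gives the familiar
S-shaped curve spanning about six orders of magnitude. The housekeeping
proteome is defined as the proteins that sit in the top abundance decile of
every cell line. It is derived from all identified (artifact-filtered)
proteins, not the quantification-filtered subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ConfigurationError, FeatureTable


@dataclass
class AbundanceRanking:
    """Per-line summed iBAQ, global median iBAQ and the dynamic range.

    ``per_line``: protein x cell-line frame of replicate-summed iBAQ (missing
    counted as 0). ``global_median``: median over all samples, the ranking
    key. ``dynamic_range_orders``: log10 span of the positive global medians.
    """

    per_line: pd.DataFrame
    global_median: pd.Series
    dynamic_range_orders: float

    def ranked(self) -> pd.Series:
        """Total order: descending global median, ties by ascending protein id."""
        frame = self.global_median.rename("ibaq").to_frame()
        frame["fid"] = frame.index
        frame = frame.sort_values(["ibaq", "fid"], ascending=[False, True])
        return frame["ibaq"]


def rank_abundance(table: FeatureTable) -> AbundanceRanking:
    if table.ibaq is None:
        raise ConfigurationError("table has no iBAQ columns; abundance needs the proteome layer")
    design = table.design
    per_line = pd.DataFrame(
        {
            line: table.ibaq[design.samples_for_line(line)].fillna(0.0).sum(axis=1)
            for line in design.cell_lines
        }
    )
    global_median = table.ibaq.median(axis=1, skipna=True).fillna(0.0)
    positive = global_median[global_median > 0]
    dynamic = float(np.log10(positive.max() / positive.min())) if len(positive) else 0.0
    return AbundanceRanking(per_line, global_median.rename("median_ibaq"), dynamic)


@dataclass
class HousekeepingResult:
    per_line_top: dict[str, list[str]]
    intersection: list[str]
    top_size: int


def housekeeping_set(ranking: AbundanceRanking, top_fraction: float = 0.10) -> HousekeepingResult:
    """Top-decile proteins per cell line and their intersection.

    Each line contributes its floor(top_fraction * N) most abundant proteins
    (per-line replicate-summed iBAQ; ties broken by global median, then id);
    the intersection across lines is the housekeeping proteome.
    """
    if not 0 < top_fraction <= 1:
        raise ConfigurationError(f"top_fraction must be in (0, 1], not {top_fraction}")
    n = len(ranking.per_line)
    if n == 0:
        raise ConfigurationError("empty abundance ranking")
    size = max(int(np.floor(top_fraction * n)), 1)
    per_line_top: dict[str, list[str]] = {}
    common: set[str] | None = None
    for line in ranking.per_line.columns:
        frame = pd.DataFrame(
            {
                "line_sum": ranking.per_line[line],
                "global_median": ranking.global_median,
                "fid": ranking.per_line.index,
            }
        ).sort_values(["line_sum", "global_median", "fid"], ascending=[False, False, True])
        top = frame.index[:size].tolist()
        per_line_top[line] = top
        common = set(top) if common is None else common & set(top)
    return HousekeepingResult(
        per_line_top=per_line_top,
        intersection=sorted(common or set()),
        top_size=size,
    )
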