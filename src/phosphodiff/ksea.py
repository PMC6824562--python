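"""Kinase-substrate enrichment from CR-vs-CS phosphosite fold changes.

Site scores are built from raw (unnormalized) SILAC ratios: per site, the
fold change of each castration-resistant line's replicate mean over the
sensitive line's replicate mean. Only sites deregulated consistently (same
direction in both CR lines) are kept; their mean fold change is min-max
rescaled to [0, 1] for reporting.

The enrichment statistic for a kinase with m matched substrate sites is

    z = (mean_substrates - mean_all) * sqrt(m) / sd_all

with a normal-tail p-value (two-sided by default). z is invariant to affine
rescaling of the score vector, so scoring on the log2 mean fold change
(which symmetrizes up and down) and reporting the [0, 1] value changes
nothing about significance. A kinase is called significant when it has at
least ``min_substrates`` matched sites and p < alpha (no multiple-testing
correction by default, matching common practice for this statistic).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg
from .tables import ConfigurationError, FeatureTable

log = logging.getLogger(__name__)


def build_site_scores(
    phospho_raw: FeatureTable,
    cs_line: str | None = None,
    cr_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Per-site fold changes of each CR line vs the CS line, consistency-gated.

    A site enters only with >= 1 valid value in each involved line. Returns a
    frame indexed by site id with one ``fc_<line>`` column per CR line plus
    ``mean_fc`` (linear), ``log2_mean_fc`` and ``normalized_fc`` in [0, 1];
    only consistent sites are retained.
    """
    design = phospho_raw.design
    cs = cs_line or design.cs_line
    crs = cr_lines or design.cr_lines
    ratios = phospho_raw.ratios
    cs_mean = ratios[design.samples_for_line(cs)].mean(axis=1, skipna=True)
    fcs = pd.DataFrame(index=ratios.index)
    for line in crs:
        line_mean = ratios[design.samples_for_line(line)].mean(axis=1, skipna=True)
        fcs[f"fc_{line}"] = line_mean / cs_mean
    fcs = fcs.dropna()
    consistent = (fcs > 1).all(axis=1) | (fcs < 1).all(axis=1)
    fcs = fcs[consistent]
    if len(fcs) < 2:
        raise ConfigurationError(
            f"only {len(fcs)} consistent sites; min-max normalization needs >= 2"
        )
    fcs["mean_fc"] = fcs.mean(axis=1)
    lo, hi = fcs["mean_fc"].min(), fcs["mean_fc"].max()
    fcs["normalized_fc"] = (fcs["mean_fc"] - lo) / (hi - lo) if hi > lo else 0.5
    fcs["log2_mean_fc"] = np.log2(fcs["mean_fc"])
    log.info("build_site_scores: %d consistent sites retained", len(fcs))
    return fcs


def read_ks_map(path) -> pd.DataFrame:
    """Two-column kinase->substrate TSV (kinase, site key like ``GENE_S123``)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["kinase", "site"], dtype=str)
    if frame.empty:
        raise ConfigurationError(f"empty kinase-substrate map: {path}")
    return frame


def kinase_zscore(scores: np.ndarray, substrate_scores: np.ndarray) -> float:
    """Enrichment z for one kinase against the global score distribution."""
    mean_all = float(np.mean(scores))
    sd_all = float(np.std(scores, ddof=1))
    m = len(substrate_scores)
    if sd_all == 0:
        return 0.0
    return (float(np.mean(substrate_scores)) - mean_all) * np.sqrt(m) / sd_all


def ksea(
    site_scores: pd.DataFrame,
    ks_map: pd.DataFrame,
    min_substrates: int = 3,
    alpha: float = 0.05,
    score_column: str = "log2_mean_fc",
    two_sided: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Kinase activity table, one row per kinase with >= 1 matched substrate.

    Returns columns kinase, m, mean_sub, z, p, significant, sorted by
    descending z. ``adjust=True`` applies BH across kinases before gating.
    Sites shared by several kinases contribute to each.
    """
    if ks_map.empty:
        raise ConfigurationError("empty kinase-substrate map")
    scores = site_scores[score_column]
    rows = []
    for kinase, sub in ks_map.groupby("kinase"):
        matched = scores.reindex(sub["site"].unique()).dropna()
        if matched.empty:
            continue
        z = kinase_zscore(scores.to_numpy(), matched.to_numpy())
        p = 2 * stats.norm.sf(abs(z)) if two_sided else stats.norm.sf(z)
        rows.append((kinase, len(matched), float(matched.mean()), z, float(p)))
    out = pd.DataFrame(rows, columns=["kinase", "m", "mean_sub", "z", "p"])
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    gate_p = benjamini_hochberg(out["p"].to_numpy()) if adjust else out["p"].to_numpy()
    out["significant"] = (out["m"] >= min_substrates) & (gate_p < alpha)
    return out.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
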