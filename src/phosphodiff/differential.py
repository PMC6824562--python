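"""Hypothesis-driven biomarker calling.

Five selection rules operate on the normalized (or log2) expression matrix:

* one-way ANOVA across the four cell lines (q <= 0.01);
* per-line two-sample t-tests of each cancer line against the benign
  reference (q <= 0.1, Welch by default), giving up/down sets;
* the resistance rule: a feature is CR_up (CR_down) iff it is significant
  with the same direction in *both* castration-resistant-vs-sensitive
  pairwise comparisons;
* the oncogenic rule: features up (down) in all three cancer lines vs the
  reference;
* the presence/absence rescue: features that failed the stringent
  quantification filter but have >= 2 valid values in the CR (CS) lines and
  strictly none in the CS (CR) line are rescued as CR_only (CS_only).

Each comparison is its own Benjamini-Hochberg family; p-values are two-sided
and direction comes from the sign of the mean difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedTable
from .tables import ConfigurationError, FeatureTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# statistics primitives


def benjamini_hochberg(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Step-up FDR-adjusted p-values (monotone, capped at 1).

    q_(i) = min_{j >= i} ( n * p_(j) / j ) for order statistics p_(1)<=...<=p_(n).
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ConfigurationError("benjamini_hochberg expects a 1-D vector")
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ConfigurationError("p-values must be finite and within [0, 1]")
    n = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _row_nanmean(X: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """NaN-aware row means over the given columns; NaN where no valid values."""
    sub = X[:, cols]
    n = np.sum(~np.isnan(sub), axis=1)
    total = np.nansum(sub, axis=1)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def _group_stats(X: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise (count, mean, ddof-1 variance) over the given columns, NaN-aware."""
    sub = X[:, cols]
    n = np.sum(~np.isnan(sub), axis=1).astype(float)
    mean = _row_nanmean(X, cols)
    with np.errstate(invalid="ignore"):
        ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
    var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def oneway_f(X: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects F-test per row.

    Returns (F, p, ok) where ok marks rows with >= 2 valid values in every
    group and positive within-group variance degrees of freedom.
    """
    k = len(groups)
    ns, means, _ = zip(*(_group_stats(X, g) for g in groups))
    ns = np.stack(ns)          # k x rows
    means = np.stack(means)
    ok = (ns >= 2).all(axis=0)
    N = ns.sum(axis=0)
    grand = np.nansum(ns * means, axis=0) / N
    ssb = np.nansum(ns * (means - grand) ** 2, axis=0)
    ssw = np.zeros(X.shape[0], dtype=float)
    for g, m in zip(groups, means):
        sub = X[:, g]
        ssw += np.nansum((sub - m[:, None]) ** 2, axis=1)
    dfb = k - 1
    dfw = N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ok & (dfw > 0), F, np.nan)
    p = np.where(np.isnan(F), np.nan, stats.f.sf(F, dfb, dfw))
    # all-equal-means with zero within variance -> F = nan via 0/0; treat as 0/p=1
    degenerate = ok & (ssw == 0) & (ssb == 0)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    return F, p, ok & ~np.isnan(p)


def two_sample_t(
    X: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray, flavor: str = "welch"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test per row (a minus b).

    Returns (t, p, mean_diff, ok); ``flavor`` is "welch" (unequal variances,
    Satterthwaite df) or "student" (pooled variance).
    """
    if flavor not in ("welch", "student"):
        raise ConfigurationError(f"unknown t-test flavor {flavor!r}")
    n1, m1, v1 = _group_stats(X, cols_a)
    n2, m2, v2 = _group_stats(X, cols_b)
    ok = (n1 >= 2) & (n2 >= 2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if flavor == "welch":
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = pooled * (1 / n1 + 1 / n2)
            df = n1 + n2 - 2
        t = diff / np.sqrt(se2)
    p = np.where(ok & np.isfinite(t), 2 * stats.t.sf(np.abs(t), df), np.nan)
    degenerate = ok & (se2 == 0) & (diff == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    ok = ok & ~np.isnan(p)
    return t, p, diff, ok


# ---------------------------------------------------------------------------
# result containers


@dataclass
class BiomarkerSets:
    """Named feature lists produced by the selection rules."""

    anova_significant: list[str] = field(default_factory=list)
    per_line_up: dict[str, list[str]] = field(default_factory=dict)
    per_line_down: dict[str, list[str]] = field(default_factory=dict)
    cr_up: list[str] = field(default_factory=list)
    cr_down: list[str] = field(default_factory=list)
    common_up: list[str] = field(default_factory=list)
    common_down: list[str] = field(default_factory=list)
    cr_only: list[str] = field(default_factory=list)
    cs_only: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "anova_significant": self.anova_significant,
            "per_line_up": self.per_line_up,
            "per_line_down": self.per_line_down,
            "CR_up": self.cr_up,
            "CR_down": self.cr_down,
            "common_up": self.common_up,
            "common_down": self.common_down,
            "CR_only": self.cr_only,
            "CS_only": self.cs_only,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BiomarkerSets":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            anova_significant=d.get("anova_significant", []),
            per_line_up=d.get("per_line_up", {}),
            per_line_down=d.get("per_line_down", {}),
            cr_up=d.get("CR_up", []),
            cr_down=d.get("CR_down", []),
            common_up=d.get("common_up", []),
            common_down=d.get("common_down", []),
            cr_only=d.get("CR_only", []),
            cs_only=d.get("CS_only", []),
        )


def _result_frame(
    index: pd.Index,
    comparison: str,
    statistic: np.ndarray,
    p: np.ndarray,
    diff: np.ndarray | None,
    means: dict[str, np.ndarray],
    alpha: float,
) -> pd.DataFrame:
    """Assemble a per-comparison table with BH within the tested family."""
    out = pd.DataFrame(index=index)
    out["comparison"] = comparison
    for name, values in means.items():
        out[f"mean_{name}"] = values
    out["statistic"] = statistic
    out["p"] = p
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    if diff is None:
        out["direction"] = "none"
    else:
        sig = tested & (out["q"] <= alpha)
        out["direction"] = np.where(
            sig & (diff > 0), "up", np.where(sig & (diff < 0), "down", "none")
        )
    # stable presentation: ascending p, ties by feature id, untested rows last
    out["_fid"] = out.index
    out = out.sort_values(["p", "_fid"], kind="stable", na_position="last").drop(columns="_fid")
    return out


# ---------------------------------------------------------------------------
# selection rules


def anova_across_lines(norm: NormalizedTable, alpha: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA of expression across the cell lines; BH across features.

    Returns one row per feature with F, p, q and ``significant``; features
    with any group under 2 valid values are reported untested.
    """
    design = norm.design
    X = norm.values.to_numpy()
    col_idx = {s: i for i, s in enumerate(norm.values.columns)}
    groups = [
        np.array([col_idx[s] for s in design.samples_for_line(line)])
        for line in design.cell_lines
    ]
    F, p, ok = oneway_f(X, groups)
    if (~ok).any():
        log.info("anova_across_lines: %d features skipped (a line has <2 valid values)",
                 int((~ok).sum()))
    means = {
        line: _row_nanmean(X, g) for line, g in zip(design.cell_lines, groups)
    }
    frame = _result_frame(norm.values.index, "anova", F, p, None, means, alpha)
    frame["significant"] = frame["q"] <= alpha
    return frame


def vs_reference(
    norm: NormalizedTable,
    reference_line: str | None = None,
    alpha: float = 0.1,
    flavor: str = "welch",
) -> dict[str, pd.DataFrame]:
    """Two-sample t-test of each cancer line against the benign reference.

    One BH family per line. Direction: up if the line mean exceeds the
    reference mean.
    """
    design = norm.design
    ref = reference_line or design.reference_line
    if ref not in design.cell_lines:
        raise ConfigurationError(f"reference line {ref!r} not in design")
    X = norm.values.to_numpy()
    col_idx = {s: i for i, s in enumerate(norm.values.columns)}
    ref_cols = np.array([col_idx[s] for s in design.samples_for_line(ref)])
    results: dict[str, pd.DataFrame] = {}
    for line in design.cell_lines:
        if line == ref:
            continue
        cols = np.array([col_idx[s] for s in design.samples_for_line(line)])
        t, p, diff, ok = two_sample_t(X, cols, ref_cols, flavor=flavor)
        means = {line: _row_nanmean(X, cols), ref: _row_nanmean(X, ref_cols)}
        results[line] = _result_frame(
            norm.values.index, f"{line}_vs_{ref}", t, p, diff, means, alpha
        )
    return results


def up_down_sets(frame: pd.DataFrame) -> tuple[list[str], list[str]]:
    up = frame.index[frame["direction"] == "up"].tolist()
    down = frame.index[frame["direction"] == "down"].tolist()
    return sorted(up), sorted(down)


def resistance_markers(
    norm: NormalizedTable,
    cs_line: str | None = None,
    cr_lines: list[str] | None = None,
    alpha: float = 0.1,
    flavor: str = "welch",
) -> tuple[list[str], list[str], dict[str, pd.DataFrame]]:
    """CR_up / CR_down: significant with the same direction in every
    CR-vs-CS pairwise comparison.

    Direction is expressed CR-relative: CR_up means higher in the
    castration-resistant lines than in the sensitive one. The benign
    reference plays no role here. Returns (cr_up, cr_down, per-comparison
    frames).
    """
    design = norm.design
    cs = cs_line or design.cs_line
    crs = cr_lines or design.cr_lines
    if len(crs) < 1:
        raise ConfigurationError("resistance rule needs at least one CR line")
    X = norm.values.to_numpy()
    col_idx = {s: i for i, s in enumerate(norm.values.columns)}
    cs_cols = np.array([col_idx[s] for s in design.samples_for_line(cs)])
    frames: dict[str, pd.DataFrame] = {}
    up_sets, down_sets = [], []
    for line in crs:
        cols = np.array([col_idx[s] for s in design.samples_for_line(line)])
        t, p, diff, ok = two_sample_t(X, cols, cs_cols, flavor=flavor)
        means = {line: _row_nanmean(X, cols), cs: _row_nanmean(X, cs_cols)}
        frame = _result_frame(norm.values.index, f"{line}_vs_{cs}", t, p, diff, means, alpha)
        frames[line] = frame
        up, down = up_down_sets(frame)
        up_sets.append(set(up))
        down_sets.append(set(down))
    cr_up = sorted(set.intersection(*up_sets)) if up_sets else []
    cr_down = sorted(set.intersection(*down_sets)) if down_sets else []
    return cr_up, cr_down, frames


def common_oncogenic_markers(
    per_line_up: dict[str, list[str]], per_line_down: dict[str, list[str]]
) -> tuple[list[str], list[str]]:
    """Features deregulated the same way in every cancer line vs the reference."""
    ups = [set(v) for v in per_line_up.values()]
    downs = [set(v) for v in per_line_down.values()]
    common_up = sorted(set.intersection(*ups)) if ups else []
    common_down = sorted(set.intersection(*downs)) if downs else []
    return common_up, common_down


def presence_absence_rescue(
    raw_filtered_out: FeatureTable,
    cs_line: str | None = None,
    cr_lines: list[str] | None = None,
    min_valid: int = 2,
) -> tuple[list[str], list[str]]:
    """Rescue identified-but-unquantifiable features as CR_only / CS_only.

    CR_only: >= ``min_valid`` valid values across the CR lines' samples and
    strictly none in the CS line's samples; CS_only symmetric. Operates on
    the features rejected by the stringent valid-value filter (a feature
    passing that filter can satisfy neither rule). The benign reference
    line's samples are ignored.
    """
    design = raw_filtered_out.design
    cs = cs_line or design.cs_line
    crs = cr_lines or design.cr_lines
    cs_samples = design.samples_for_line(cs)
    cr_samples = [s for line in crs for s in design.samples_for_line(line)]
    valid = raw_filtered_out.ratios.notna()
    n_cr = valid[cr_samples].sum(axis=1)
    n_cs = valid[cs_samples].sum(axis=1)
    cr_only = raw_filtered_out.feature_ids[(n_cr >= min_valid) & (n_cs == 0)]
    cs_only = raw_filtered_out.feature_ids[(n_cs >= min_valid) & (n_cr == 0)]
    return sorted(cr_only), sorted(cs_only)
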