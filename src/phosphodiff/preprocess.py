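"""Normalization, the stringent valid-value filter, sample clustering and
cross-layer correlation.

The pipeline order is fixed: artifact filter -> valid-value filter -> log2 ->
z-score, so that z-scores are computed only on quantifiable, artifact-free
rows. Missing values are never imputed; distances and correlations are
computed pairwise-complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .tables import ConfigurationError, FeatureTable, StudyDesign

log = logging.getLogger(__name__)


@dataclass
class NormalizedTable:
    """Z-scores of base-2 log ratios, with the normalization axis recorded.

    ``values`` is a feature x sample frame; NaN marks missing. Per
    normalization axis the valid entries have mean ~0 and SD ~1 (zero-variance
    slices normalize to 0 instead of erroring, so degenerate inputs pass
    through).
    """

    values: pd.DataFrame
    design: StudyDesign
    layer: str
    axis: str  # "sample" | "feature"
    gene_symbols: pd.Series | None = None

    @property
    def valid_mask(self) -> pd.DataFrame:
        return self.values.notna()


class FilterResult(NamedTuple):
    kept: FeatureTable
    removed: FeatureTable


def log2_zscore(table: FeatureTable, axis: str = "sample") -> NormalizedTable:
    """Base-2 logarithmize the ratios, then z-score along ``axis``.

    ``axis="sample"`` standardizes each column (removes SILAC channel mixing
    offsets); ``axis="feature"`` each row. Missing stays missing; a
    zero-variance slice maps to all zeros.
    """
    if axis not in ("sample", "feature"):
        raise ConfigurationError(f"axis must be 'sample' or 'feature', not {axis!r}")
    with np.errstate(invalid="ignore"):
        bad = (table.ratios <= 0).any(axis=1)
    if bad.any():
        raise ConfigurationError(
            f"non-positive ratio for feature {table.feature_ids[bad][0]!r}"
        )
    logged = np.log2(table.ratios)
    pandas_axis = 0 if axis == "sample" else 1
    mean = logged.mean(axis=pandas_axis)
    sd = logged.std(axis=pandas_axis, ddof=1)
    centered = logged.sub(mean, axis=1 - pandas_axis)
    z = centered.div(sd.where(sd > 0), axis=1 - pandas_axis)
    z = z.where(z.notna(), centered * 0.0)  # zero-variance slices -> 0, NaN stays NaN
    return NormalizedTable(
        values=z, design=table.design, layer=table.layer, axis=axis,
        gene_symbols=table.gene_symbols,
    )


def valid_value_filter(table: FeatureTable, min_valid_per_line: int = 2) -> FilterResult:
    """Keep features with >= ``min_valid_per_line`` valid values in every cell line.

    This is the stringent quantification filter; the rejected features are
    returned too, because the presence/absence rescue operates on them.
    """
    design = table.design
    for line in design.cell_lines:
        n = len(design.samples_for_line(line))
        if min_valid_per_line > n:
            raise ConfigurationError(
                f"min_valid_per_line={min_valid_per_line} exceeds the "
                f"{n} replicates of cell line {line!r}"
            )
    ok = pd.Series(True, index=table.feature_ids)
    for line in design.cell_lines:
        cols = design.samples_for_line(line)
        ok &= table.ratios[cols].notna().sum(axis=1) >= min_valid_per_line
    log.info(
        "valid_value_filter: %d of %d features have >=%d valid values in all %d lines",
        int(ok.sum()), len(table), min_valid_per_line, len(design.cell_lines),
    )
    return FilterResult(
        kept=table.subset(table.feature_ids[ok]),
        removed=table.subset(table.feature_ids[~ok]),
    )


# ---------------------------------------------------------------------------
# hierarchical clustering of samples


@dataclass
class Dendrogram:
    """Average-linkage dendrogram over samples.

    ``linkage`` is the SciPy merge matrix (heights in Euclidean-distance
    units); ``replicate_coherence`` the fraction of cell lines whose
    replicates form a single subtree.
    """

    linkage: np.ndarray
    labels: list[str]
    replicate_coherence: float

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def _pairwise_complete_distances(values: pd.DataFrame) -> np.ndarray:
    """Condensed Euclidean distances on shared-valid features, scaled by
    sqrt(total/shared) so pairs with different coverage stay comparable."""
    X = values.to_numpy()
    n_feat, n_samp = X.shape
    out = []
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            shared = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            m = int(shared.sum())
            if m == 0:
                raise ConfigurationError(
                    f"samples {values.columns[i]!r} and {values.columns[j]!r} "
                    "share no valid features"
                )
            d = np.sqrt(np.sum((X[shared, i] - X[shared, j]) ** 2) * (n_feat / m))
            out.append(d)
    return np.asarray(out)


def _coherence(linkage: np.ndarray, labels: list[str], design: StudyDesign) -> float:
    """Fraction of cell lines whose samples are exactly one subtree's leaves."""
    n = len(labels)
    leafsets: list[frozenset[str]] = [frozenset([lab]) for lab in labels]
    for a, b, *_ in linkage:
        leafsets.append(leafsets[int(a)] | leafsets[int(b)])
    available = set(leafsets)
    hits = 0
    lines = design.cell_lines
    for line in lines:
        if frozenset(design.samples_for_line(line)) in available:
            hits += 1
    return hits / len(lines)


def hierarchical_cluster(norm: NormalizedTable) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of samples on Euclidean distances."""
    if norm.values.shape[1] < 2:
        raise ConfigurationError("need at least 2 samples to cluster")
    dist = _pairwise_complete_distances(norm.values)
    linkage = sch.linkage(dist, method="average")
    labels = list(norm.values.columns)
    return Dendrogram(
        linkage=linkage,
        labels=labels,
        replicate_coherence=_coherence(linkage, labels, norm.design),
    )


# ---------------------------------------------------------------------------
# proteome / phosphoproteome correlation


def cross_layer_correlation(
    prot: NormalizedTable, phos: NormalizedTable
) -> tuple[pd.Series, int]:
    """Per-cell-line Pearson correlation between protein expression and the
    mean phosphorylation of the protein's sites.

    Phosphosite accessions (the part before the residue suffix) are mapped to
    protein groups; per cell line the protein value is the mean over
    replicates, the phospho value the mean over the protein's sites then over
    replicates. Returns (per-line correlations, number of shared proteins).
    """
    # accession -> protein feature id (protein groups may list several accessions)
    acc_to_protein: dict[str, str] = {}
    for fid in prot.values.index:
        for acc in str(fid).split(";"):
            acc_to_protein.setdefault(acc, fid)

    parents = phos.values.index.str.rsplit("_", n=1).str[0]
    mapped = parents.map(lambda a: acc_to_protein.get(a))
    site_ok = mapped.notna()

    design = prot.design
    per_line: dict[str, float] = {}
    shared_counts = []
    phos_by_parent = phos.values.loc[site_ok].groupby(mapped[site_ok]).mean()
    for line in design.cell_lines:
        p_cols = design.samples_for_line(line)
        f_cols = phos.design.samples_for_line(line)
        prot_mean = prot.values.loc[:, p_cols].mean(axis=1)
        phos_mean = phos_by_parent.loc[:, f_cols].mean(axis=1)
        both = pd.concat([prot_mean, phos_mean], axis=1, join="inner").dropna()
        shared_counts.append(len(both))
        if len(both) < 3:
            raise ConfigurationError(
                f"fewer than 3 shared proteins with values in cell line {line!r}"
            )
        per_line[line] = float(both.iloc[:, 0].corr(both.iloc[:, 1]))
    return pd.Series(per_line, name="pearson_r"), int(min(shared_counts))
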