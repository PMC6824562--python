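"""Module-activity scoring: PC1 weights, overdispersion, and group summaries.

For each gene set, expression of the matched genes (rows centered across
samples) is decomposed; the first principal component provides per-gene
weights and the per-sample activity score is the weighted sum of expression.
L1, the fraction of the set's variance captured by PC1, measures how
coordinated the set is; its significance ("overdispersion") is assessed
against random gene sets of the same size drawn from the measured universe.
Group activity (CS vs CR) is the mean sample score per group, scaled
per module so the larger magnitude is +/-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedTable
from .tables import ConfigurationError, StudyDesign

log = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT format: name <tab> description <tab> gene symbols..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


@dataclass
class ModuleActivityResult:
    name: str
    genes_used: list[str]
    weights: pd.Series          # unit-norm PC1 loadings per used gene
    L1: float                   # in [1/k, 1]
    sample_scores: pd.Series
    p_overdispersion: float | None = None


def _complete_submatrix(norm: NormalizedTable, genes: list[str]) -> pd.DataFrame | None:
    """Rows of the matrix for the set's genes with no missing sample."""
    symbols = norm.gene_symbols
    if symbols is None:
        raise ConfigurationError("normalized table carries no gene symbols")
    primary = symbols.fillna("").str.split(";").str[0]
    hit = primary.isin(set(genes))
    sub = norm.values.loc[hit.index[hit]]
    sub = sub.dropna(axis=0, how="any")
    sub.index = primary.loc[sub.index]
    # a symbol measured twice (two protein groups) keeps its first occurrence
    sub = sub[~sub.index.duplicated(keep="first")]
    return sub


def _pc1(sub: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """PC1 of a genes x samples block: (unit weights, L1, sample scores)."""
    centered = sub - sub.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / max(sub.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    trace = float(np.sum(evals))
    w = evecs[:, -1]
    L1 = float(evals[-1] / trace) if trace > 0 else 1.0 / sub.shape[0]
    # orient so the weights correlate positively with the mean expression profile
    mean_profile = centered.mean(axis=0)
    scores = w @ centered
    if np.dot(scores, mean_profile) < 0:
        w, scores = -w, -scores
    return w, L1, scores


def module_score(norm: NormalizedTable, name: str, genes: list[str],
                 min_genes: int = 3) -> ModuleActivityResult | None:
    """Score one gene set; returns None (logged) when <3 genes match completely."""
    sub = _complete_submatrix(norm, genes)
    if sub is None or len(sub) < min_genes:
        log.info("module %s skipped: %d matched genes (< %d)",
                 name, 0 if sub is None else len(sub), min_genes)
        return None
    w, L1, scores = _pc1(sub.to_numpy())
    return ModuleActivityResult(
        name=name,
        genes_used=list(sub.index),
        weights=pd.Series(w, index=sub.index, name="pc1_weight"),
        L1=L1,
        sample_scores=pd.Series(scores, index=norm.values.columns, name=name),
    )


def overdispersion_test(
    norm: NormalizedTable,
    genes: list[str],
    n_null: int = 1000,
    seed: int | np.random.Generator = 0,
    min_genes: int = 3,
) -> tuple[float, float] | None:
    """Permutation p-value for L1 against random same-size gene sets.

    Null sets are drawn without replacement from the genes measured with
    complete values; p = (1 + #{null L1 >= observed}) / (n_null + 1).
    Returns (observed L1, p) or None when the set cannot be scored.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = _complete_submatrix(norm, genes)
    if sub is None or len(sub) < min_genes:
        return None
    k = len(sub)
    primary = norm.gene_symbols.fillna("").str.split(";").str[0]
    universe = norm.values.copy()
    universe.index = primary
    universe = universe.dropna(axis=0, how="any")
    universe = universe[~universe.index.duplicated(keep="first")]
    if k > len(universe):
        raise ConfigurationError(
            f"gene set ({k}) larger than the measured complete-value universe ({len(universe)})"
        )
    _, observed, _ = _pc1(sub.to_numpy())
    U = universe.to_numpy()
    exceed = 0
    for _ in range(n_null):
        pick = rng.choice(len(U), size=k, replace=False)
        _, null_l1, _ = _pc1(U[pick])
        if null_l1 >= observed - 1e-12:  # tolerance: row order must not matter
            exceed += 1
    return observed, (1 + exceed) / (n_null + 1)


def score_collection(
    norm: NormalizedTable,
    gene_sets: dict[str, list[str]],
    n_null: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    min_genes: int = 3,
) -> tuple[list[ModuleActivityResult], pd.DataFrame]:
    """Score every set and test overdispersion; returns (results, summary table)."""
    rng = np.random.default_rng(seed)
    results = []
    rows = []
    for name, genes in gene_sets.items():
        res = module_score(norm, name, genes, min_genes=min_genes)
        if res is None:
            continue
        od = overdispersion_test(norm, genes, n_null=n_null, seed=rng, min_genes=min_genes)
        res.p_overdispersion = od[1] if od else None
        results.append(res)
        rows.append((name, len(res.genes_used), res.L1, res.p_overdispersion,
                     res.p_overdispersion is not None and res.p_overdispersion <= alpha))
    table = pd.DataFrame(rows, columns=["module", "k", "L1", "p_overdispersion", "overdispersed"])
    return results, table


def group_summary(
    results: list[ModuleActivityResult],
    design: StudyDesign,
    groups: tuple[str, ...] = ("CS", "CR"),
) -> pd.DataFrame:
    """Per-module group means of sample scores, scaled per module to [-1, 1].

    Each module's group values are divided by their max absolute value, so
    the stronger group sits at +/-1 (positive = higher activity).
    """
    rows = []
    for res in results:
        values = {}
        for group in groups:
            samples = design.samples_in_group(group)
            if not samples:
                raise ConfigurationError(f"no samples in group {group!r}")
            values[group] = float(res.sample_scores[samples].mean())
        peak = max(abs(v) for v in values.values())
        scaled = {g: (v / peak if peak > 0 else 0.0) for g, v in values.items()}
        rows.append({"module": res.name, **scaled})
    return pd.DataFrame(rows).set_index("module")
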