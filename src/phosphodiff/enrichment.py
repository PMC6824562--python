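"""Background-constrained over-representation analysis (ORA).

Terms are tested with the hypergeometric upper tail on counts restricted to
the supplied background (for this pipeline: the quantification-filtered
feature universe, not the whole genome). BH is applied across the tested
terms of one collection, and a Jaccard-overlap pass suppresses redundant
annotations, keeping only the most significant term of each overlap group.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import pandas as pd
from scipy import stats

from .tables import ConfigurationError
from .differential import benjamini_hochberg

log = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ConfigurationError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query: Iterable[str],
    collections: dict[str, list[str]],
    background: Iterable[str],
    alpha: float = 0.01,
    jaccard_redundancy: float | None = 0.75,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each term, within ``background``.

    Query genes outside the background are logged and dropped; term gene sets
    are intersected with the background before counting. Returns a frame with
    term, k, n, K, N, p, q, significant, redundant and the overlapping genes,
    sorted by p. When ``jaccard_redundancy`` is set, terms whose
    background-restricted gene sets overlap with a more significant kept term
    at Jaccard >= the threshold are marked redundant.
    """
    bg = set(background)
    if not bg:
        raise ConfigurationError("empty background")
    q_all = set(query)
    dropped = q_all - bg
    if dropped:
        log.info("ora: dropping %d query genes outside the background", len(dropped))
    q = q_all & bg
    n, N = len(q), len(bg)
    rows = []
    for term, genes in collections.items():
        term_bg = set(genes) & bg
        if not term_bg:
            continue
        overlap = sorted(q & term_bg)
        k, K = len(overlap), len(term_bg)
        rows.append(
            {
                "term": term, "k": k, "n": n, "K": K, "N": N,
                "p": hypergeom_upper_tail(k, n, K, N),
                "genes": ";".join(overlap),
                "_members": frozenset(term_bg),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "q", "significant", "redundant", "genes"]
        )
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    redundant = [False] * len(out)
    if jaccard_redundancy is not None:
        kept: list[frozenset] = []
        for i, members in enumerate(out["_members"]):
            for other in kept:
                jac = len(members & other) / len(members | other)
                if jac >= jaccard_redundancy:
                    redundant[i] = True
                    break
            if not redundant[i]:
                kept.append(members)
    out["redundant"] = redundant
    return out.drop(columns="_members")
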