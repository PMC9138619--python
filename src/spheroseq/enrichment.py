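"""Hypergeometric gene-set enrichment and core-pathway selection.

Enrichment of a DEG list against a named gene-set collection uses the
upper tail of the hypergeometric distribution (probability of drawing at
least k set members when n genes are drawn from a universe of N containing
K set members), with Benjamini-Hochberg correction across the sets of one
query. Sets significant at FDR < 0.01; "core" sets are those recurrently
in the per-condition top ranks with very small raw p (default < 1e-11).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

__all__ = [
    "GeneSetCollection",
    "hypergeom_pvalue",
    "enrich",
    "select_core_pathways",
    "set_overlap_pct",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Members falling outside the universe are dropped at construction
    (harmonization); empty sets are kept out by the readers.
    """

    sets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.sets = {name: frozenset(members) & self.universe for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, np.finfo(float).tiny))


def enrich(
    degs: Iterable[str],
    collection: GeneSetCollection,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Enrichment table for one DEG list against a collection.

    DEGs outside the universe are dropped with a warning. Returns one row
    per set (k, K, n, N, pvalue, fdr, significant), sorted by (fdr, pvalue).
    """
    if not collection.universe:
        raise ValueError("empty background universe")
    degs = set(degs)
    outside = degs - collection.universe
    if outside:
        logger.warning("%d query genes outside the universe were dropped", len(outside))
    degs &= collection.universe
    n = len(degs)
    N = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(degs & members)
        rows.append((name, k, K, n, N, hypergeom_pvalue(k, K, n, N)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "pvalue"]).set_index("set")
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy()) if len(table) else []
    table["significant"] = table["fdr"] < fdr_max
    return table.sort_values(["fdr", "pvalue"])


def select_core_pathways(
    results: Mapping[str, pd.DataFrame],
    p_cutoff: float = 1e-11,
    top_k: int = 4,
) -> list[str]:
    """Recurrent deeply-enriched sets across conditions.

    Per condition, the ``top_k`` sets by FDR-corrected p are taken; a set
    qualifies if its raw p is below ``p_cutoff`` in every condition where
    it makes the top ranks. Qualifying sets are returned by descending
    appearance frequency, ties broken by the best raw p.
    """
    if not results:
        raise ValueError("at least one condition required")
    freq: dict[str, int] = {}
    best_p: dict[str, float] = {}
    qualified: dict[str, bool] = {}
    for table in results.values():
        top = table.sort_values(["fdr", "pvalue"]).head(top_k)
        for name, row in top.iterrows():
            freq[name] = freq.get(name, 0) + 1
            best_p[name] = min(best_p.get(name, 1.0), float(row["pvalue"]))
            qualified[name] = qualified.get(name, True) and float(row["pvalue"]) < p_cutoff
    keep = [s for s in freq if qualified[s]]
    return sorted(keep, key=lambda s: (-freq[s], best_p[s]))


def set_overlap_pct(a: Iterable[str], b: Iterable[str], denominator: str = "a") -> float:
    """|a ∩ b| as a percentage of one of the sets, one-decimal rounding.

    ``denominator`` selects which set's size divides the intersection.
    Returns NaN when the denominator set is empty.
    """
    a, b = set(a), set(b)
    den = a if denominator == "a" else b
    if denominator not in ("a", "b"):
        raise ValueError("denominator must be 'a' or 'b'")
    if not den:
        return float("nan")
    return round(100.0 * len(a & b) / len(den), 1)
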