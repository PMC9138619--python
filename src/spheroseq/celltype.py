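"""Cell-type marker derivation and bulk-DEG attribution.

The reference is a mean-expression table of genes x (cell type, brain
region), emulating what one obtains by averaging a single-cell atlas per
annotated cell type and region. Within a region, a gene is a *marker* of a
cell type when its expression there is at least ``fold`` (default 10) times
its expression in every other cell type of that region; a zero-expressed
gene is never a marker. A bulk DEG list is attributed to cell types by the
fraction of each type's markers it contains, averaged over regions.

Reference table layout: DataFrame indexed by gene, columns named
``"<cell_type>@<region>"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MarkerCatalog",
    "split_reference_columns",
    "derive_markers",
    "attribution_scores",
    "marker_deg_stability",
    "panel_overlap",
]


@dataclass
class MarkerCatalog:
    """(cell_type, region) -> marker gene set, plus the fold used."""

    markers: dict[tuple[str, str], frozenset]
    fold: float

    def cell_types(self) -> list[str]:
        return sorted({ct for ct, _ in self.markers})

    def regions(self) -> list[str]:
        return sorted({r for _, r in self.markers})

    def n_markers(self, cell_type: str, region: str) -> int:
        return len(self.markers.get((cell_type, region), frozenset()))


def split_reference_columns(columns: Iterable[str]) -> list[tuple[str, str]]:
    """Parse ``cell_type@region`` column labels."""
    out = []
    for col in columns:
        if "@" not in col:
            raise ValueError(f"reference column {col!r} is not of the form 'cell_type@region'")
        ct, region = col.split("@", 1)
        out.append((ct, region))
    return out


def derive_markers(
    reference: pd.DataFrame,
    fold: float = 10.0,
    mode: str = "max",
) -> MarkerCatalog:
    """Fold-specificity markers per cell type within each region.

    ``mode="max"`` (default) requires expr(g, c) >= fold * expr(g, c') for
    every other cell type c' — equivalently against the max of the others;
    ``mode="mean"`` compares against the mean of the others instead. The
    comparison is inclusive ("at least ten-fold lower") and zero-expressed
    genes are never markers. Within a region marker sets of different cell
    types are disjoint by construction (fold > 1 means at most one cell
    type can dominate).
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    pairs = split_reference_columns(reference.columns)
    regions: dict[str, list[tuple[str, str]]] = {}
    for (ct, region), col in zip(pairs, reference.columns):
        regions.setdefault(region, []).append((ct, col))

    markers: dict[tuple[str, str], frozenset] = {}
    for region, ct_cols in regions.items():
        if len(ct_cols) < 2:
            raise ValueError(f"region {region!r} has fewer than 2 cell types")
        mat = reference[[col for _, col in ct_cols]].to_numpy(dtype=float)
        for j, (ct, _) in enumerate(ct_cols):
            own = mat[:, j]
            others = np.delete(mat, j, axis=1)
            ref_level = others.max(axis=1) if mode == "max" else others.mean(axis=1)
            hit = (own > 0) & (own >= fold * ref_level)
            markers[(ct, region)] = frozenset(reference.index[hit])
    return MarkerCatalog(markers=markers, fold=fold)


def attribution_scores(
    catalog: MarkerCatalog,
    deg_catalog: Mapping[tuple[str, int], pd.Series],
) -> pd.DataFrame:
    """Fraction of each cell type's markers present in each DEG list.

    Per region the score is |markers ∩ DEGs| / |markers|; the reported
    score averages over the regions with a non-empty marker set (empty
    marker sets contribute no region). Returns a tidy DataFrame with
    columns cytokine, timepoint, cell_type, score, n_regions.
    """
    rows = []
    for (cytokine, timepoint), directions in deg_catalog.items():
        degs = set(directions.index)
        for ct in catalog.cell_types():
            per_region = []
            for region in catalog.regions():
                m = catalog.markers.get((ct, region), frozenset())
                if m:
                    per_region.append(len(m & degs) / len(m))
            score = float(np.mean(per_region)) if per_region else float("nan")
            rows.append((cytokine, timepoint, ct, score, len(per_region)))
    return pd.DataFrame(rows, columns=["cytokine", "timepoint", "cell_type", "score", "n_regions"])


def marker_deg_stability(
    catalog: MarkerCatalog,
    deg_catalog: Mapping[tuple[str, int], pd.Series],
    cell_type: str,
    cytokine: str,
) -> pd.DataFrame:
    """Overlap of a cell type's DEG-markers across stimulation time points.

    S_t = (markers of the cell type, pooled over regions) ∩ DEGs(t); for
    each pair of time points the Jaccard percentage |S_t1 ∩ S_t2| /
    |S_t1 ∪ S_t2| * 100 is reported (NaN when both sets are empty).
    """
    pooled = frozenset().union(
        *[catalog.markers.get((cell_type, r), frozenset()) for r in catalog.regions()]
    )
    timepoints = sorted(tp for c, tp in deg_catalog if c == cytokine)
    sets = {tp: pooled & set(deg_catalog[(cytokine, tp)].index) for tp in timepoints}
    rows = []
    for t1, t2 in combinations(timepoints, 2):
        union = sets[t1] | sets[t2]
        pct = 100.0 * len(sets[t1] & sets[t2]) / len(union) if union else float("nan")
        rows.append((t1, t2, len(sets[t1]), len(sets[t2]), pct))
    return pd.DataFrame(rows, columns=["t1", "t2", "n_t1", "n_t2", "overlap_pct"])


def panel_overlap(query: Iterable[str], panel: Iterable[str], denominator: str = "panel") -> float:
    """Percentage of a gene panel found in a query list (or vice versa).

    Default denominator is the panel, matching "overlap with genes
    associated with ..." reporting; ``denominator="query"`` gives the other
    orientation. NaN when the denominator set is empty.
    """
    query, panel = set(query), set(panel)
    if denominator not in ("panel", "query"):
        raise ValueError("denominator must be 'panel' or 'query'")
    den = panel if denominator == "panel" else query
    if not den:
        return float("nan")
    return round(100.0 * len(query & panel) / len(den), 1)
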