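"""Replicate-free two-library Poisson differential expression.

Each contrast compares one pooled stimulated library against one pooled
control library, gene by gene. Under a Poisson model for fragment counts,
conditional on the total x + y the stimulated count is binomial with
success probability N2 / (N1 + N2), where N1, N2 are the library sizes
(Audic & Claverie's exact test for SAGE/RNA-seq tag counts). The two-sided
p-value doubles the smaller inclusive tail and is capped at 1.

Genes pass the differential-expression gate when the fold change is at
least ``fc_min`` (default 2.00, i.e. |log2FC| >= 1, boundary inclusive)
and the Benjamini-Hochberg FDR is at most ``fdr_max`` (default 0.001,
boundary inclusive).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_fpkm",
    "poisson_pair_pvalue",
    "bh_fdr",
    "two_library_contrast",
    "call_degs",
    "common_degs",
    "cytokine_specific_degs",
    "shared_fraction",
]


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    FPKM(g, s) = counts(g, s) * 1e9 / (length_bp(g) * library_size(s)).
    Library sizes default to the column sums of ``counts``.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def poisson_pair_pvalue(x, y, n1, n2):
    """Two-sided p-value for a two-library count comparison.

    Conditional on the total t = x + y, y ~ Binomial(t, n2 / (n1 + n2))
    under the null of equal relative abundance. p = min(1, 2 * min(P(Y <= y),
    P(Y >= y))), tails inclusive of the observed count; t = 0 gives p = 1.
    Tails are evaluated through the regularized incomplete beta function,
    which is computed in log space internally, so deep tails do not
    underflow to 0 before the final comparison. Accepts scalars or arrays
    (broadcast together).

    Symmetry: p(x, y, n1, n2) == p(y, x, n2, n1).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be positive")
    total = x + y
    p2 = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, total, p2)
    upper = stats.binom.sf(y - 1, total, p2)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.maximum(p, np.finfo(float).tiny)  # post: p in (0, 1]
    if p.ndim == 0:
        return float(p)
    return p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and np.isnan(p).any():
        raise ValueError("NaN p-values cannot be FDR-adjusted")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def two_library_contrast(
    counts: pd.DataFrame,
    control: str,
    case: str,
    lengths: pd.Series | None = None,
    pseudocount: float = 1.0,
    fc_min: float = 2.0,
    fdr_max: float = 0.001,
) -> pd.DataFrame:
    """Full per-gene contrast table for one (control, stimulated) pair.

    Genes with zero counts in both libraries are untestable and excluded,
    mirroring the detected-gene universe of a real run. log2FC is computed
    on counts rescaled to the geometric mean of the two library sizes with
    ``pseudocount`` added to both, so genes absent from one library still
    get a finite fold change.

    Returns a DataFrame indexed by gene with columns
    x, y, n1, n2, log2fc, pvalue, fdr, is_deg, direction.
    """
    x = counts[control]
    y = counts[case]
    n1 = float(x.sum())
    n2 = float(y.sum())
    detected = (x > 0) | (y > 0)
    x = x[detected].to_numpy(dtype=float)
    y = y[detected].to_numpy(dtype=float)
    genes = counts.index[detected]

    scale = np.sqrt(n1 * n2)
    xn = x * scale / n1
    yn = y * scale / n2
    log2fc = np.log2((yn + pseudocount) / (xn + pseudocount))
    pvalue = poisson_pair_pvalue(x, y, n1, n2)
    fdr = bh_fdr(pvalue)
    table = pd.DataFrame(
        {
            "x": x.astype(np.int64),
            "y": y.astype(np.int64),
            "n1": n1,
            "n2": n2,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
        },
        index=genes,
    )
    table.index.name = "gene_id"
    table["is_deg"] = (np.abs(table["log2fc"]) >= np.log2(fc_min)) & (table["fdr"] <= fdr_max)
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return table


def call_degs(contrast: pd.DataFrame, fc_min: float = 2.0, fdr_max: float = 0.001) -> pd.Series:
    """DEG directions from a contrast table.

    A gene is a DEG iff |log2FC| >= log2(fc_min) and FDR <= fdr_max, both
    boundaries inclusive. Returns a Series gene -> {"up", "down"}.
    """
    keep = (contrast["log2fc"].abs() >= np.log2(fc_min)) & (contrast["fdr"] <= fdr_max)
    sub = contrast.loc[keep, "log2fc"]
    return pd.Series(np.where(sub >= 0, "up", "down"), index=sub.index, name="direction")


DEGCatalog = Mapping[tuple[str, int], pd.Series]
"""(cytokine, timepoint) -> Series of DEG directions indexed by gene."""


def _union(catalog: DEGCatalog, cytokine: str) -> set:
    keys = [k for k in catalog if k[0] == cytokine]
    out: set = set()
    for k in keys:
        out |= set(catalog[k].index)
    return out


def common_degs(catalog: DEGCatalog, cytokine_a: str = "TNFA", cytokine_b: str = "IL1B") -> set:
    """Genes in at least one DEG list of each cytokine.

    (union over cytokine-a time points) ∩ (union over cytokine-b time points).
    """
    for c in (cytokine_a, cytokine_b):
        if not any(k[0] == c for k in catalog):
            raise ValueError(f"catalog has no DEG lists for cytokine {c!r}")
    return _union(catalog, cytokine_a) & _union(catalog, cytokine_b)


def cytokine_specific_degs(
    catalog: DEGCatalog,
    log2fc_profiles: Mapping[str, pd.DataFrame],
    abs_log2fc_min: float = 1.5,
    cytokine_a: str = "TNFA",
    cytokine_b: str = "IL1B",
) -> tuple[set, set]:
    """Strictly cytokine-specific DEG categories.

    Category A: genes in at least one cytokine-a DEG list, in none of
    cytokine-b's, with |log2FC| strictly above ``abs_log2fc_min`` at some
    cytokine-a time point. Category B is the mirror image.
    """
    a_all = _union(catalog, cytokine_a)
    b_all = _union(catalog, cytokine_b)

    def _filter(genes: set, cytokine: str) -> set:
        prof = log2fc_profiles[cytokine]
        present = [g for g in genes if g in prof.index]
        if not present:
            return set()
        mx = prof.loc[present].abs().max(axis=1)
        return set(mx.index[mx > abs_log2fc_min])

    category_a = _filter(a_all - b_all, cytokine_a)
    category_b = _filter(b_all - a_all, cytokine_b)
    return category_a, category_b


def shared_fraction(
    catalog: DEGCatalog,
    timepoint: int,
    cytokine_a: str = "TNFA",
    cytokine_b: str = "IL1B",
) -> tuple[float, float]:
    """Percentage of each cytokine's DEG list shared with the other at one time point.

    Returns (|A∩B|/|A|*100, |A∩B|/|B|*100) rounded to the nearest integer;
    an empty list yields NaN for its side.
    """
    a = set(catalog[(cytokine_a, timepoint)].index)
    b = set(catalog[(cytokine_b, timepoint)].index)
    inter = len(a & b)
    pa = round(100.0 * inter / len(a)) if a else float("nan")
    pb = round(100.0 * inter / len(b)) if b else float("nan")
    return pa, pb
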