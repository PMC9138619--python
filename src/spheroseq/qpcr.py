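"""Relative qPCR quantification and RNA-seq cross-validation.

Relative expression per primer follows Q_x = mu_eff^(ct_min - ct_x), where
mu_eff is the primer's mean amplification efficiency (2 = perfect
doubling), ct_min the minimum take-off cycle across the samples of that
primer and ct_x the sample's take-off cycle; Q is therefore in (0, 1] with
the most abundant sample at 1. Target Q-values are normalized per sample
to the geometric mean of the reference-gene Q-values (GAPDH/YWHAZ-style
two-gene normalizer), fold changes are ratios of normalized condition
means, and agreement with RNA-seq log2FC is scored by a one-tailed
(positive-association) Pearson correlation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "normalize_to_references",
    "qpcr_log2fc",
    "validate_correlation",
    "analyze_plate",
]


def relative_expression(ct_values, mu_eff: float) -> np.ndarray:
    """Q_x = mu_eff^(ct_min - ct_x) over one primer's samples; Q in (0, 1]."""
    if mu_eff <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct = np.asarray(ct_values, dtype=float)
    if ct.size == 0:
        raise ValueError("at least one ct value required")
    return np.power(mu_eff, ct.min() - ct)


def normalize_to_references(q_target: pd.Series, q_refs: pd.DataFrame) -> pd.Series:
    """Divide target Q by the per-sample geometric mean of reference-gene Q."""
    q_refs = q_refs.reindex(q_target.index)
    if (q_refs <= 0).any().any() or q_refs.isna().any().any():
        raise ValueError("reference-gene Q values must be positive for every sample")
    gmean = np.exp(np.log(q_refs).mean(axis=1))
    return q_target / gmean


def qpcr_log2fc(normalized: pd.Series, conditions: pd.Series, control: str) -> pd.Series:
    """log2 of condition-mean over control-mean, per stimulated condition.

    ``normalized`` is indexed by sample; ``conditions`` maps sample ->
    condition label. Means are over the replicate samples of a condition.
    """
    conditions = conditions.reindex(normalized.index)
    means = normalized.groupby(conditions).mean()
    if control not in means.index:
        raise ValueError(f"control condition {control!r} absent")
    if means[control] <= 0:
        raise ValueError("control mean must be positive")
    out = np.log2(means.drop(index=control) / means[control])
    out.name = "log2fc"
    return out


def validate_correlation(rnaseq_log2fc, qpcr_log2fc_values) -> tuple[float, float]:
    """One-tailed Pearson correlation (alternative: r > 0) of paired log2FCs.

    Returns (r, p); (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(rnaseq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired vectors of equal length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def analyze_plate(
    plate: pd.DataFrame,
    reference_genes: Sequence[str] = ("GAPDH", "YWHAZ"),
    control: str = "CTRL_0h",
    efficiencies: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Plate records -> per-gene, per-condition log2 fold changes.

    ``plate`` columns: sample, condition, primer, ct and optionally
    efficiency. Technical replicates of one (sample, primer) are averaged
    on the ct scale before quantification. Efficiencies come from the
    plate's efficiency column unless overridden; absent either, 2.0 is
    assumed with a warning. Returns a DataFrame genes x conditions of
    reference-normalized log2FC relative to ``control``.
    """
    required = {"sample", "condition", "primer", "ct"}
    if not required <= set(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    missing_refs = set(reference_genes) - set(plate["primer"])
    if missing_refs:
        raise ValueError(f"reference genes missing from plate: {sorted(missing_refs)}")

    eff: dict[str, float] = {}
    if "efficiency" in plate.columns:
        eff.update(plate.groupby("primer")["efficiency"].mean().to_dict())
    if efficiencies:
        eff.update(efficiencies)

    ct = plate.groupby(["primer", "sample"])["ct"].mean().unstack("sample")
    cond = plate.drop_duplicates("sample").set_index("sample")["condition"]

    q = {}
    for primer, row in ct.iterrows():
        mu = eff.get(primer)
        if mu is None or np.isnan(mu):
            import logging

            logging.getLogger(__name__).warning(
                "no efficiency for primer %s; assuming perfect doubling (2.0)", primer
            )
            mu = 2.0
        vals = row.dropna()
        q[primer] = pd.Series(relative_expression(vals.to_numpy(), mu), index=vals.index)
    q_df = pd.DataFrame(q)  # samples x primers

    refs = q_df[list(reference_genes)]
    out = {}
    for primer in q_df.columns:
        if primer in reference_genes:
            continue
        normalized = normalize_to_references(q_df[primer], refs)
        out[primer] = qpcr_log2fc(normalized, cond, control)
    result = pd.DataFrame(out).T
    result.index.name = "gene_id"
    return result
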