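"""Boolean band clustering of log2 fold-change time courses.

Each gene's stimulation time course (log2FC at 4 h, 12 h and 36 h relative
to the unstimulated control) is discretised into a triplet of bands split
at 0 and at a strong-response threshold (default 2.5 log2 units):

    SU  strong up     log2FC >= +threshold
    MU  mild up       0 < log2FC < +threshold   (exact 0 maps here)
    MD  mild down     -threshold < log2FC < 0
    SD  strong down   log2FC <= -threshold

A cluster is a distinct band triplet. In *discovery* mode every observed
triplet defines a cluster, so all genes are clustered by construction; in
*definition* mode only genes matching a supplied pattern list are assigned
and the clustered fraction per cytokine is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "DEFAULT_PATTERNS",
    "assign_band",
    "assign_pattern",
    "cluster_profiles",
    "cluster_overlap_pct",
    "ClusterSummary",
]

BANDS = ("SU", "MU", "MD", "SD")

#: Default pattern vocabulary: 22 band triplets covering sustained, transient
#: and late responses in both directions plus mixed-direction courses. The
#: two all-mild patterns (ids 8 and 22) absorb genes whose course never
#: leaves the (-threshold, +threshold) band.
DEFAULT_PATTERNS: tuple[tuple[str, str, str], ...] = (
    ("SU", "SU", "SU"),
    ("SU", "SU", "MU"),
    ("SU", "MU", "MU"),
    ("SU", "MU", "SU"),
    ("MU", "SU", "SU"),
    ("MU", "SU", "MU"),
    ("MU", "MU", "SU"),
    ("MU", "MU", "MU"),
    ("SD", "SD", "SD"),
    ("SD", "SD", "MD"),
    ("SD", "MD", "MD"),
    ("SD", "MD", "SD"),
    ("MD", "SD", "SD"),
    ("MD", "SD", "MD"),
    ("MD", "MD", "SD"),
    ("MD", "MD", "MU"),
    ("SU", "MU", "MD"),
    ("MU", "MD", "MD"),
    ("MD", "MU", "MU"),
    ("SU", "MD", "MD"),
    ("MU", "MU", "MD"),
    ("MD", "MD", "MD"),
)


def assign_band(log2fc: float, threshold: float = 2.5) -> str:
    """Map a single log2FC value to its band.

    Boundary convention: values at exactly +/-threshold fall in the strong
    band ("a threshold of 2.5" is inclusive for the strong response, the
    mild bands being the open intervals around 0); exactly 0 maps to MU.

    Raises ``ValueError`` on NaN.
    """
    if math.isnan(log2fc):
        raise ValueError("log2FC is NaN; bands are defined for finite values only")
    if log2fc >= threshold:
        return "SU"
    if log2fc <= -threshold:
        return "SD"
    return "MU" if log2fc >= 0 else "MD"


def assign_pattern(log2fcs: Sequence[float], threshold: float = 2.5) -> tuple[str, ...]:
    """Band triplet (or n-tuple) for one gene's time course."""
    return tuple(assign_band(float(v), threshold) for v in log2fcs)


@dataclass
class ClusterSummary:
    """Result of Boolean clustering across cytokines.

    Attributes
    ----------
    clusters : mapping cluster_id -> pattern (band tuple)
    members : mapping cluster_id -> {cytokine: frozenset of gene ids}
    unclustered : mapping cytokine -> frozenset of unassigned gene ids
    pct_clustered : mapping cytokine -> percentage of that cytokine's
        profiles assigned to a cluster
    """

    clusters: dict[int, tuple[str, ...]]
    members: dict[int, dict[str, frozenset]] = field(default_factory=dict)
    unclustered: dict[str, frozenset] = field(default_factory=dict)
    pct_clustered: dict[str, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self, cytokine: str) -> dict[int, int]:
        return {cid: len(m.get(cytokine, frozenset())) for cid, m in self.members.items()}


def cluster_profiles(
    profiles: Mapping[str, pd.DataFrame],
    definitions: Sequence[tuple[str, ...]] | None = None,
    threshold: float = 2.5,
) -> ClusterSummary:
    """Cluster per-cytokine log2FC time courses by band pattern.

    Parameters
    ----------
    profiles : mapping cytokine -> DataFrame (genes x ordered time points)
        of log2FC values relative to 0 h. Typically restricted to the
        common DEG set. Missing values are treated as 0 (a gene that is not
        a DEG at a time point contributes no fold change).
    definitions : optional list of band patterns. When given, genes whose
        pattern is not in the list are reported unclustered; cluster ids are
        1-based positions in the list. Without definitions, clusters are
        the distinct observed patterns (every gene assigned).
    """
    if definitions is not None:
        if len(set(definitions)) != len(definitions):
            raise ValueError("duplicate pattern definitions")
        definitions = [tuple(p) for p in definitions]

    patterns: dict[str, dict[str, tuple[str, ...]]] = {}
    for cytokine, df in profiles.items():
        filled = df.fillna(0.0)
        per_gene = {}
        for gene, row in zip(filled.index, filled.to_numpy()):
            per_gene[str(gene)] = assign_pattern(row, threshold)
        patterns[cytokine] = per_gene

    if definitions is None:
        observed = sorted({p for d in patterns.values() for p in d.values()})
        clusters = {i + 1: pat for i, pat in enumerate(observed)}
    else:
        clusters = {i + 1: pat for i, pat in enumerate(definitions)}
    by_pattern = {pat: cid for cid, pat in clusters.items()}

    members: dict[int, dict[str, frozenset]] = {cid: {} for cid in clusters}
    unclustered: dict[str, frozenset] = {}
    pct: dict[str, float] = {}
    for cytokine, per_gene in patterns.items():
        assigned: dict[int, set] = {cid: set() for cid in clusters}
        missed = set()
        for gene, pat in per_gene.items():
            cid = by_pattern.get(pat)
            if cid is None:
                missed.add(gene)
            else:
                assigned[cid].add(gene)
        for cid in clusters:
            members[cid][cytokine] = frozenset(assigned[cid])
        unclustered[cytokine] = frozenset(missed)
        total = len(per_gene)
        pct[cytokine] = 100.0 * (total - len(missed)) / total if total else float("nan")

    return ClusterSummary(clusters=clusters, members=members, unclustered=unclustered, pct_clustered=pct)


def cluster_overlap_pct(
    summary: ClusterSummary,
    cytokine_a: str = "TNFA",
    cytokine_b: str = "IL1B",
    below: float = 25.0,
) -> tuple[pd.Series, int]:
    """Per-cluster percentage of genes shared between the two cytokines.

    Overlap is the Jaccard percentage |A∩B| / |A∪B| * 100 of the cluster's
    memberships under each cytokine; clusters empty under both cytokines get
    NaN. Also returns the number of clusters strictly below ``below`` %.
    """
    out = {}
    for cid in summary.clusters:
        a = summary.members[cid].get(cytokine_a, frozenset())
        b = summary.members[cid].get(cytokine_b, frozenset())
        union = a | b
        out[cid] = 100.0 * len(a & b) / len(union) if union else np.nan
    ser = pd.Series(out, name="overlap_pct").sort_index()
    n_below = int((ser.dropna() < below).sum())
    return ser, n_below
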