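"""Seeded synthetic study generator with ground truth.

Emulates the design of a cytokine-stimulation experiment on a 3D neural
culture containing the major brain cell types: one pooled bulk RNA-seq
library per condition (unstimulated control plus two cytokines x three
stimulation durations), a cell-type x brain-region mean-expression
reference with planted fold-specific markers, pathway/panel gene-set
collections, and a qPCR plate with planted per-primer amplification
efficiencies. Every planted quantity is returned as ground truth so each
downstream stage of the analysis is testable without external data.

Counts are Poisson per library (matching the assumption of the
replicate-free two-library test); an optional gamma overdispersion knob
exists but is off by default. Baseline gene abundances are log-normal, so
a realistic detected-gene count and FPKM dynamic range emerge without
fitting real data. Planted time-course responses are drawn from the band
vocabulary of :mod:`spheroseq.timecourse`, making cluster recovery
testable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .timecourse import DEFAULT_PATTERNS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "BulkExperiment",
    "generate_reference_profiles",
    "generate_bulk_experiment",
    "generate_gene_sets",
    "generate_qpcr_plate",
    "simulate_study",
    "DEFAULT_MARKER_RANGES",
    "DEFAULT_MIXING",
]

DEFAULT_CELL_TYPES = ("NPC", "EXC", "IN", "AST", "OPC", "MG", "ENDO", "UNL")
DEFAULT_REGIONS = (
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "occipital_cortex",
    "non_cortical",
)

#: Markers planted per cell type and region, drawn uniformly from these
#: ranges (reported marker-count ranges of a fetal-brain single-cell atlas
#: across five regions; the unlabeled population has no reported range).
DEFAULT_MARKER_RANGES: dict[str, tuple[int, int]] = {
    "NPC": (39, 91),
    "EXC": (691, 1444),
    "IN": (152, 381),
    "AST": (92, 262),
    "OPC": (50, 71),
    "MG": (491, 708),
    "ENDO": (316, 473),
    "UNL": (80, 200),
}
_FALLBACK_MARKER_RANGE = (30, 120)

#: Cell-type mixing proportions of the pooled bulk libraries. The study
#: organism gives no measured composition; this is a plausible neural-
#: culture mixture (neuron-rich, with minor mesoderm-derived populations),
#: a free parameter rather than an estimate.
DEFAULT_MIXING: dict[str, float] = {
    "NPC": 0.15,
    "EXC": 0.30,
    "IN": 0.10,
    "AST": 0.15,
    "OPC": 0.05,
    "MG": 0.08,
    "ENDO": 0.07,
    "UNL": 0.10,
}

REFERENCE_GENES = ("GAPDH", "YWHAZ")


@dataclass
class SimulationConfig:
    n_genes: int = 18000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    timepoints: tuple[int, ...] = (0, 4, 12, 36)
    cytokines: tuple[str, ...] = ("TNFA", "IL1B")
    library_size: int = 10_000_000
    n_planted_de_per_pattern: int = 15
    n_cytokine_specific: int = 80
    effect_log2fc_range: tuple[float, float] = (0.5, 5.0)
    marker_fold: float = 10.0
    marker_count_ranges: Mapping[str, tuple[int, int]] | None = None
    mixing: Mapping[str, float] | None = None
    overdispersion: float = 0.0
    qpcr_noise_sd: float = 0.15
    qpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.cell_types) < 2:
            raise ValueError("at least 2 cell types required")
        tps = tuple(self.timepoints)
        if 0 not in tps or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing and include 0")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        lo, hi = self.effect_log2fc_range
        if not (0 < lo <= hi <= 12):
            raise ValueError("effect_log2fc_range must lie within (0, 12]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    @property
    def stim_timepoints(self) -> tuple[int, ...]:
        return tuple(t for t in self.timepoints if t > 0)

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    planted_de: dict[str, dict[str, dict]] = field(default_factory=dict)
    planted_markers: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    qpcr_efficiencies: dict[str, float] = field(default_factory=dict)

    def planted_log2fc(self, cytokine: str, timepoint: int) -> pd.Series:
        """Per-gene planted log2FC for one contrast (0 for unplanted genes)."""
        vals = {
            g: spec[cytokine]["log2fc"].get(timepoint, 0.0)
            for g, spec in self.planted_de.items()
            if cytokine in spec
        }
        return pd.Series(vals, dtype=float)

    def profile(self, cytokine: str, timepoints: Sequence[int]) -> pd.DataFrame:
        genes = [g for g, spec in self.planted_de.items() if cytokine in spec]
        data = {
            tp: [self.planted_de[g][cytokine]["log2fc"].get(tp, 0.0) for g in genes]
            for tp in timepoints
        }
        return pd.DataFrame(data, index=genes)


@dataclass
class BulkExperiment:
    counts: pd.DataFrame  # genes x samples, integer
    lengths: pd.Series  # bp per gene
    sample_meta: pd.DataFrame  # sample -> cytokine, timepoint

    @property
    def control_sample(self) -> str:
        ctrl = self.sample_meta.index[self.sample_meta["timepoint"] == 0]
        return str(ctrl[0])


def _gene_ids(n_genes: int) -> list[str]:
    ids = [f"G{i:05d}" for i in range(n_genes - len(REFERENCE_GENES))]
    return ids + list(REFERENCE_GENES)


def generate_reference_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cell-type x region mean-expression reference with planted markers.

    Per region, each cell type receives a planted marker gene set (size
    drawn from the per-type range) whose expression in that cell type is at
    least ``marker_fold`` times its expression in every other cell type;
    all remaining genes are clamped below the fold so that marker
    derivation recovers exactly the planted sets.
    """
    rng = config.rng(1)
    genes = _gene_ids(config.n_genes)
    columns = [f"{ct}@{r}" for r in config.regions for ct in config.cell_types]
    base = rng.lognormal(mean=1.0, sigma=1.2, size=(config.n_genes, len(columns)))
    ref = pd.DataFrame(base, index=genes, columns=columns)

    ranges = dict(DEFAULT_MARKER_RANGES)
    if config.marker_count_ranges:
        ranges.update(config.marker_count_ranges)

    # Housekeeping reference genes are never markers.
    plantable = np.arange(config.n_genes - len(REFERENCE_GENES))
    truth = GroundTruth()
    fold = config.marker_fold
    for region in config.regions:
        cols = {ct: f"{ct}@{region}" for ct in config.cell_types}
        sizes = {}
        for ct in config.cell_types:
            lo, hi = ranges.get(ct, _FALLBACK_MARKER_RANGE)
            sizes[ct] = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        total = sum(sizes.values())
        if total > 0.5 * len(plantable):
            scale = 0.5 * len(plantable) / total
            sizes = {ct: max(1, int(n * scale)) if n else 0 for ct, n in sizes.items()}
            total = sum(sizes.values())
        chosen = rng.choice(plantable, size=total, replace=False)
        mat = ref.loc[:, [cols[ct] for ct in config.cell_types]].to_numpy()
        offset = 0
        marker_rows: set[int] = set()
        for j, ct in enumerate(config.cell_types):
            rows = chosen[offset : offset + sizes[ct]]
            offset += sizes[ct]
            marker_rows.update(int(r) for r in rows)
            others = np.delete(mat[rows], j, axis=1)
            boost = fold * others.max(axis=1) * rng.uniform(1.05, 2.0, size=len(rows))
            mat[rows, j] = boost
            truth.planted_markers[(ct, region)] = frozenset(ref.index[rows])
        # Clamp every non-marker gene below the specificity fold.
        non_marker = np.setdiff1d(np.arange(config.n_genes), np.fromiter(marker_rows, dtype=int))
        sub = mat[non_marker]
        order = np.argsort(sub, axis=1)
        top = order[:, -1]
        second_val = sub[np.arange(len(sub)), order[:, -2]]
        top_val = sub[np.arange(len(sub)), top]
        too_high = top_val >= fold * second_val
        sub[np.arange(len(sub)), top] = np.where(too_high, 0.9 * fold * second_val, top_val)
        mat[non_marker] = sub
        ref.loc[:, [cols[ct] for ct in config.cell_types]] = mat
    return ref, truth


def _draw_band_log2fc(band: str, rng: np.random.Generator, lo: float, hi: float) -> float:
    strong_hi = max(hi, 3.5)
    mild_lo = min(max(lo, 0.05), 2.3)
    if band == "SU":
        return float(rng.uniform(2.5, strong_hi))
    if band == "SD":
        return float(-rng.uniform(2.5, strong_hi))
    if band == "MU":
        return float(rng.uniform(mild_lo, 2.4))
    return float(-rng.uniform(mild_lo, 2.4))


def generate_bulk_experiment(
    config: SimulationConfig,
    reference: pd.DataFrame,
    truth: GroundTruth,
) -> tuple[BulkExperiment, GroundTruth]:
    """Pooled count matrix: one library per (cytokine, timepoint) plus control.

    Baseline expected expression is the cell-type mixture of the reference
    (averaged over regions); planted response genes have their expected
    count scaled by 2^log2FC at each stimulation time point, with the
    per-time-point log2FC drawn inside its planted band; counts are Poisson
    per library. Responses are planted on moderately expressed genes
    (expected control counts roughly 30-1000), keeping realized library
    sizes within a few percent of the configured depth.
    """
    missing = [ct for ct in config.cell_types if not any(c.startswith(f"{ct}@") for c in reference.columns)]
    if missing:
        raise ValueError(f"reference does not cover cell types {missing}")
    rng = config.rng(2)
    genes = list(reference.index)
    n = len(genes)

    mixing = dict(config.mixing) if config.mixing else None
    if mixing is None:
        if set(config.cell_types) <= set(DEFAULT_MIXING):
            mixing = {ct: DEFAULT_MIXING[ct] for ct in config.cell_types}
        else:
            mixing = {ct: 1.0 for ct in config.cell_types}
    w_total = sum(mixing.values())

    baseline = np.zeros(n)
    for ct in config.cell_types:
        cols = [c for c in reference.columns if c.startswith(f"{ct}@")]
        baseline += (mixing[ct] / w_total) * reference[cols].mean(axis=1).to_numpy()
    frac = baseline / baseline.sum()

    # Plant responses on moderately expressed genes only.
    expected_ctrl = frac * config.library_size
    eligible = np.flatnonzero((expected_ctrl >= 30) & (expected_ctrl <= 1000))
    eligible = eligible[~np.isin(np.array(genes)[eligible], REFERENCE_GENES)]
    patterns = DEFAULT_PATTERNS
    n_common = config.n_planted_de_per_pattern * len(patterns)
    strong_patterns = [p for p in patterns if "SU" in p or "SD" in p]
    n_specific = config.n_cytokine_specific * len(config.cytokines)
    need = n_common + n_specific
    if need > len(eligible):
        raise ValueError(
            f"cannot plant {need} response genes among {len(eligible)} eligible genes; "
            "increase n_genes or library_size"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    lo, hi = config.effect_log2fc_range
    stim_tps = config.stim_timepoints

    def plant(gene: str, cytokine: str, pattern: tuple[str, ...]) -> None:
        fcs = {
            tp: _draw_band_log2fc(band, rng, lo, hi)
            for tp, band in zip(stim_tps, pattern)
        }
        truth.planted_de.setdefault(gene, {})[cytokine] = {"pattern": pattern, "log2fc": fcs}

    cyt_a, cyt_b = (list(config.cytokines) + [None, None])[:2]
    idx = 0
    for pat in patterns:
        for _ in range(config.n_planted_de_per_pattern):
            g = genes[chosen[idx]]
            idx += 1
            plant(g, cyt_a, pat)
            if cyt_b is not None:
                plant(g, cyt_b, patterns[rng.integers(len(patterns))])
    for cytokine in config.cytokines:
        for _ in range(config.n_cytokine_specific):
            g = genes[chosen[idx]]
            idx += 1
            plant(g, cytokine, strong_patterns[rng.integers(len(strong_patterns))])

    # Build expected-count matrix and draw Poisson libraries.
    samples = ["CTRL_0h"] + [f"{c}_{t}h" for c in config.cytokines for t in stim_tps]
    meta = pd.DataFrame(
        {
            "cytokine": ["NONE"] + [c for c in config.cytokines for _ in stim_tps],
            "timepoint": [0] + [t for _ in config.cytokines for t in stim_tps],
        },
        index=pd.Index(samples, name="sample"),
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    lam = np.tile((frac * config.library_size)[:, None], (1, len(samples)))
    for g, per_cyt in truth.planted_de.items():
        i = gene_pos[g]
        for cytokine, spec in per_cyt.items():
            for tp, fc in spec["log2fc"].items():
                s = samples.index(f"{cytokine}_{tp}h")
                lam[i, s] *= 2.0**fc
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    lengths = pd.Series(
        rng.integers(300, 20001, size=n), index=counts_df.index, name="length_bp"
    )
    return BulkExperiment(counts=counts_df, lengths=lengths, sample_meta=meta), truth


def generate_gene_sets(
    config: SimulationConfig,
    truth: GroundTruth,
    universe: Iterable[str],
    n_background: int = 30,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Pathway-like and panel-like gene-set collections (GMT emulation).

    Three "core" inflammation-signaling sets are loaded with planted
    response genes (so deep enrichment is recoverable), with the TNF- and
    NFkB-like sets sharing roughly a quarter of their members; background
    sets are random draws. Panels emulate disease-association and
    inflammation gene lists with graded planted-response content. Returns
    (pathways, panels).
    """
    rng = config.rng(3)
    universe = sorted(set(universe))
    planted = sorted(g for g in truth.planted_de if g in set(universe))
    other = sorted(set(universe) - set(planted))

    def sample(pool: Sequence[str], k: int) -> list[str]:
        k = min(k, len(pool))
        return list(rng.choice(np.asarray(pool, dtype=object), size=k, replace=False))

    sets: dict[str, frozenset] = {}
    cyto = sample(planted, 120) + sample(other, 60)
    tnf = sample(planted, 75) + sample(other, 35)
    shared = sample(tnf, 30)
    remaining = sorted(set(planted) - set(tnf))
    nfkb = shared + sample(remaining, 40) + sample(other, 25)
    sets["CYTOKINE_RECEPTOR_INTERACTION_LIKE"] = frozenset(cyto)
    sets["TNF_SIGNALING_LIKE"] = frozenset(tnf)
    sets["NFKB_SIGNALING_LIKE"] = frozenset(nfkb)
    for i in range(n_background):
        size = int(rng.integers(40, 201))
        sets[f"BACKGROUND_{i:02d}"] = frozenset(sample(universe, size))
    pathways = GeneSetCollection(sets=sets, universe=frozenset(universe))

    panel_spec = {
        "MS_PANEL": (100, 35),
        "AD_PANEL": (100, 8),
        "PD_PANEL": (100, 6),
        "NFKB_PANEL": (120, 48),
        "INFLAMMATION_PANEL": (150, 52),
        "NEUROINFLAMMATION_PANEL": (160, 32),
    }
    panels: dict[str, frozenset] = {}
    for name, (size, n_planted) in panel_spec.items():
        members = sample(planted, n_planted) + sample(other, size - n_planted)
        panels[name] = frozenset(members)
    return pathways, GeneSetCollection(sets=panels, universe=frozenset(universe))


def generate_qpcr_plate(
    truth: GroundTruth,
    genes: Sequence[str],
    config: SimulationConfig,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulated qPCR plate records for a gene panel.

    ``genes`` must include the two housekeeping reference genes (planted
    log2FC 0 in every condition). Per primer, an amplification efficiency
    mu_eff is drawn in (1.85, 2.0] and take-off cycles satisfy
    ct = ct0 - log2FC(condition) / log2(mu_eff) plus Gaussian noise
    (default sd 0.15 cycles), so ct drops by 1/log2(mu_eff) per doubling
    of true abundance. Returns a tidy plate DataFrame with columns
    sample, condition, primer, ct, efficiency.
    """
    missing = [g for g in REFERENCE_GENES if g not in genes]
    if missing:
        raise ValueError(f"gene panel must include reference genes; missing {missing}")
    rng = config.rng(4)
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    conditions = ["CTRL_0h"] + [
        f"{c}_{t}h" for c in config.cytokines for t in config.stim_timepoints
    ]
    records = []
    for gene in genes:
        eff = float(rng.uniform(1.85, 2.0))
        truth.qpcr_efficiencies[gene] = eff
        ct0 = float(rng.uniform(20.0, 28.0))
        for cond in conditions:
            fc = 0.0
            if gene in truth.planted_de and cond != "CTRL_0h":
                cytokine, tp = cond[:-1].rsplit("_", 1)
                spec = truth.planted_de[gene].get(cytokine)
                if spec is not None:
                    fc = spec["log2fc"].get(int(tp), 0.0)
            base_ct = ct0 - fc / np.log2(eff)
            for rep in range(config.qpcr_replicates):
                ct = base_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                records.append((f"{cond}_r{rep + 1}", cond, gene, ct, eff))
    return pd.DataFrame(records, columns=["sample", "condition", "primer", "ct", "efficiency"])


def default_qpcr_panel(truth: GroundTruth, config: SimulationConfig, n_targets: int = 10) -> list[str]:
    """A validation panel: responsive genes spanning both cytokines, plus references."""
    rng = config.rng(5)
    strong = sorted(
        g
        for g, per_cyt in truth.planted_de.items()
        if len(per_cyt) == len(config.cytokines)
        and max(abs(v) for spec in per_cyt.values() for v in spec["log2fc"].values()) >= 1.0
    )
    n_targets = min(n_targets, len(strong))
    picked = list(rng.choice(np.asarray(strong, dtype=object), size=n_targets, replace=False))
    return picked + list(REFERENCE_GENES)


def simulate_study(config: SimulationConfig):
    """Full synthetic study: reference, bulk counts, gene sets, qPCR plate, truth."""
    reference, truth = generate_reference_profiles(config)
    bulk, truth = generate_bulk_experiment(config, reference, truth)
    detected = bulk.counts.index[(bulk.counts > 0).any(axis=1)]
    pathways, panels = generate_gene_sets(config, truth, detected)
    panel_genes = default_qpcr_panel(truth, config)
    plate = generate_qpcr_plate(truth, panel_genes, config)
    return reference, bulk, pathways, panels, plate, truth
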