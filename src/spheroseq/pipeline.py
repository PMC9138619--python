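"""End-to-end analysis driver.

Runs the full study workflow over either simulated inputs (seeded) or
user-supplied files: per-condition two-library contrasts and DEG calling,
pathway enrichment with core-pathway selection, common-DEG extraction and
cytokine-specific categories, Boolean time-course clustering, cell-type
marker attribution, panel overlaps, and qPCR validation. Produces a
machine-readable summary of the headline numbers and, when an output
directory is given, TSV/GMT/JSON artifacts re-readable by this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import celltype, diffexpr, enrichment, io, qpcr, timecourse
from .simulate import REFERENCE_GENES, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one pipeline run.

    Leave ``counts_path`` unset to run in simulate mode, in which case
    ``sim`` (or its seed) defines the synthetic study.
    """

    counts_path: str | None = None
    reference_path: str | None = None
    pathways_gmt: str | None = None
    panels_gmt: str | None = None
    plate_path: str | None = None
    outdir: str | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fc_min: float = 2.0
    fdr_max: float = 0.001
    pseudocount: float = 1.0
    enrich_fdr: float = 0.01
    core_p: float = 1e-11
    top_k: int = 4
    band_threshold: float = 2.5
    specific_abs_log2fc: float = 1.5
    marker_fold: float = 10.0
    skip_enrichment: bool = False

    def __post_init__(self) -> None:
        for name in ("fc_min", "fdr_max", "enrich_fdr", "core_p", "band_threshold", "specific_abs_log2fc", "marker_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.counts_path is None:
        reference, bulk, pathways, panels, plate, truth = simulate_study(config.sim)
        return reference, bulk, pathways, panels, plate, truth
    bulk = io.read_counts(config.counts_path)
    reference = io.read_reference(config.reference_path) if config.reference_path else None
    detected = frozenset(bulk.counts.index[(bulk.counts > 0).any(axis=1)])
    pathways = io.read_gmt(config.pathways_gmt, universe=detected) if config.pathways_gmt else None
    panels = io.read_gmt(config.panels_gmt, universe=detected) if config.panels_gmt else None
    plate = io.read_plate(config.plate_path) if config.plate_path else None
    return reference, bulk, pathways, panels, plate, None


@_stage("diffexpr")
def _contrast_stage(config: PipelineConfig, bulk):
    control = bulk.control_sample
    contrasts: dict[tuple[str, int], pd.DataFrame] = {}
    catalog: dict[tuple[str, int], pd.Series] = {}
    for sample, row in bulk.sample_meta.iterrows():
        if row["timepoint"] <= 0:
            continue
        table = diffexpr.two_library_contrast(
            bulk.counts,
            control=control,
            case=sample,
            pseudocount=config.pseudocount,
            fc_min=config.fc_min,
            fdr_max=config.fdr_max,
        )
        key = (str(row["cytokine"]), int(row["timepoint"]))
        contrasts[key] = table
        catalog[key] = diffexpr.call_degs(table, config.fc_min, config.fdr_max)
        logger.info(
            "%s_%dh: %d genes tested, %d DEGs", key[0], key[1], len(table), len(catalog[key])
        )
    return contrasts, catalog


def _log2fc_profiles(contrasts) -> dict[str, pd.DataFrame]:
    profiles: dict[str, dict[int, pd.Series]] = {}
    for (cytokine, tp), table in contrasts.items():
        profiles.setdefault(cytokine, {})[tp] = table["log2fc"]
    return {c: pd.DataFrame(cols).sort_index(axis=1) for c, cols in profiles.items()}


@_stage("enrichment")
def _enrichment_stage(config: PipelineConfig, catalog, pathways):
    if pathways is None:
        raise ValueError("enrichment requested but no pathway GMT available")
    results = {}
    for (cytokine, tp), degs in catalog.items():
        results[f"{cytokine}_{tp}h"] = enrichment.enrich(
            set(degs.index), pathways, fdr_max=config.enrich_fdr
        )
    core = enrichment.select_core_pathways(results, p_cutoff=config.core_p, top_k=config.top_k)
    core_overlaps = {}
    for a in core:
        for b in core:
            if a < b:
                core_overlaps[f"{a} in {b}"] = enrichment.set_overlap_pct(
                    pathways.sets[a], pathways.sets[b], denominator="a"
                )
    return results, core, core_overlaps


@_stage("timecourse")
def _timecourse_stage(config: PipelineConfig, catalog, contrasts, cytokines):
    common = diffexpr.common_degs(catalog, *cytokines)
    profiles = _log2fc_profiles(contrasts)
    common_profiles = {
        c: df.reindex(sorted(common)) for c, df in profiles.items() if c in cytokines
    }
    summary = timecourse.cluster_profiles(common_profiles, threshold=config.band_threshold)
    overlap, n_below = timecourse.cluster_overlap_pct(summary, *cytokines)
    return common, profiles, summary, overlap, n_below


@_stage("celltype")
def _celltype_stage(config: PipelineConfig, reference, catalog, panels, cytokines):
    if reference is None:
        return None, None, {}, {}
    markers = celltype.derive_markers(reference, fold=config.marker_fold)
    attribution = celltype.attribution_scores(markers, catalog)
    unions = {
        c: frozenset().union(*[set(v.index) for k, v in catalog.items() if k[0] == c])
        for c in cytokines
    }
    panel_pcts: dict[str, dict[str, float]] = {}
    if panels is not None:
        for name, members in panels.sets.items():
            panel_pcts[name] = {
                c: celltype.panel_overlap(unions[c], members, denominator="panel")
                for c in cytokines
            }
    stability = {}
    for c in cytokines:
        tps = sorted(tp for cyt, tp in catalog if cyt == c)
        if len(tps) == 3:
            for ct in markers.cell_types():
                table = celltype.marker_deg_stability(markers, catalog, ct, c)
                stability[f"{ct}_{c}"] = round(float(table["overlap_pct"].mean()), 1)
    return markers, attribution, panel_pcts, stability


@_stage("qpcr")
def _qpcr_stage(plate, contrasts):
    if plate is None:
        return None, {}
    fc = qpcr.analyze_plate(plate, reference_genes=REFERENCE_GENES, control="CTRL_0h")
    correlations = {}
    for (cytokine, tp), table in contrasts.items():
        col = f"{cytokine}_{tp}h"
        if col not in fc.columns:
            continue
        paired = fc[col].dropna()
        rnaseq = table["log2fc"].reindex(paired.index)
        keep = rnaseq.notna()
        if keep.sum() >= 3:
            r, p = qpcr.validate_correlation(rnaseq[keep], paired[keep])
            correlations[col] = {"r": round(r, 4), "p_one_tailed": p, "n": int(keep.sum())}
    return fc, correlations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the machine-readable summary."""
    reference, bulk, pathways, panels, plate, truth = _load_inputs(config)
    fpkm = diffexpr.compute_fpkm(bulk.counts, bulk.lengths)
    contrasts, catalog = _contrast_stage(config, bulk)
    cytokines = tuple(
        dict.fromkeys(c for c, _ in catalog)  # preserve order of appearance
    )

    summary: dict = {
        "n_genes_detected": int((bulk.counts > 0).any(axis=1).sum()),
        "library_sizes": {s: int(v) for s, v in bulk.counts.sum(axis=0).items()},
        "deg_counts": {},
    }
    for (cytokine, tp), degs in sorted(catalog.items()):
        n_up = int((degs == "up").sum())
        n_down = int((degs == "down").sum())
        summary["deg_counts"][f"{cytokine}_{tp}h"] = {
            "total": len(degs),
            "up": n_up,
            "down": n_down,
        }

    enrich_results = core = None
    if not config.skip_enrichment:
        enrich_results, core, core_overlaps = _enrichment_stage(config, catalog, pathways)
        summary["core_pathways"] = core
        summary["core_pathway_overlap_pct"] = core_overlaps

    common, profiles, clusters, cluster_overlap, n_low_overlap = _timecourse_stage(
        config, catalog, contrasts, cytokines
    )
    summary["n_common_degs"] = len(common)
    summary["n_clusters"] = clusters.n_clusters
    summary["pct_clustered"] = {c: round(v, 2) for c, v in clusters.pct_clustered.items()}
    summary["n_clusters_overlap_below_25pct"] = n_low_overlap

    cat_a, cat_b = diffexpr.cytokine_specific_degs(
        catalog, profiles, abs_log2fc_min=config.specific_abs_log2fc,
        cytokine_a=cytokines[0], cytokine_b=cytokines[1],
    )
    summary["category_sizes"] = {cytokines[0]: len(cat_a), cytokines[1]: len(cat_b)}
    summary["shared_pct"] = {}
    tps = sorted({tp for _, tp in catalog})
    for tp in tps:
        if all((c, tp) in catalog for c in cytokines):
            pa, pb = diffexpr.shared_fraction(catalog, tp, *cytokines)
            summary["shared_pct"][f"{tp}h"] = {cytokines[0]: pa, cytokines[1]: pb}

    markers, attribution, panel_pcts, stability = _celltype_stage(
        config, reference, catalog, panels, cytokines
    )
    if attribution is not None:
        top = (
            attribution.dropna(subset=["score"])
            .groupby("cell_type")["score"]
            .mean()
            .sort_values(ascending=False)
        )
        summary["attribution_mean_score"] = {ct: round(v, 4) for ct, v in top.items()}
        summary["panel_overlap_pct"] = panel_pcts
        summary["marker_deg_stability_pct"] = stability

    qpcr_fc, correlations = _qpcr_stage(plate, contrasts)
    if correlations:
        summary["qpcr_validation"] = correlations

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_counts(bulk, out / "counts.tsv")
        fpkm.to_csv(out / "fpkm.tsv", sep="\t", float_format="%.4f")
        for (cytokine, tp), table in contrasts.items():
            table.to_csv(out / f"contrast_{cytokine}_{tp}h.tsv", sep="\t", float_format="%.6g")
        if enrich_results is not None:
            for cond, table in enrich_results.items():
                table.to_csv(out / f"enrichment_{cond}.tsv", sep="\t", float_format="%.6g")
        io.write_gene_list(common, out / "common_degs.txt")
        io.write_gene_list(cat_a, out / f"category_{cytokines[0]}_specific.txt")
        io.write_gene_list(cat_b, out / f"category_{cytokines[1]}_specific.txt")
        if attribution is not None:
            attribution.to_csv(out / "attribution.tsv", sep="\t", index=False, float_format="%.4f")
        if qpcr_fc is not None:
            qpcr_fc.to_csv(out / "qpcr_log2fc.tsv", sep="\t", float_format="%.4f")
        io.write_json(summary, out / "summary.json")
    return summary
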