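"""Synthetic-study generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from spheroseq.celltype import derive_markers
from spheroseq.diffexpr import bh_fdr, poisson_pair_pvalue
from spheroseq.qpcr import analyze_plate
from spheroseq.simulate import (
    DEFAULT_MARKER_RANGES,
    GroundTruth,
    SimulationConfig,
    generate_bulk_experiment,
    generate_qpcr_plate,
    generate_reference_profiles,
    simulate_study,
)


class TestConfigValidation:
    def test_timepoints_must_include_zero_and_increase(self):
        with pytest.raises(ValueError):
            SimulationConfig(timepoints=(4, 12, 36))
        with pytest.raises(ValueError):
            SimulationConfig(timepoints=(0, 12, 4))

    def test_marker_fold_and_effect_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(marker_fold=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(effect_log2fc_range=(0.5, 13.0))

    def test_fewer_than_two_cell_types(self):
        with pytest.raises(ValueError):
            SimulationConfig(cell_types=("NPC",))


class TestReferenceProfiles:
    def test_tiny_config_recovers_planted_markers(self):
        cfg = SimulationConfig(
            n_genes=10,
            cell_types=("A", "B"),
            regions=("r",),
            marker_count_ranges={"A": (3, 3), "B": (0, 0)},
            seed=5,
        )
        ref, truth = generate_reference_profiles(cfg)
        markers = derive_markers(ref, fold=cfg.marker_fold)
        assert markers.markers[("A", "r")] == truth.planted_markers[("A", "r")]
        assert len(truth.planted_markers[("A", "r")]) == 3

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_genes=500, seed=9, marker_count_ranges={ct: (5, 10) for ct in SimulationConfig().cell_types})
        ref1, t1 = generate_reference_profiles(cfg)
        ref2, t2 = generate_reference_profiles(cfg)
        pd.testing.assert_frame_equal(ref1, ref2)
        assert t1.planted_markers == t2.planted_markers

    def test_default_marker_counts_within_reported_ranges(self, small_study, small_config):
        # the per-type draw respects its configured range in every region
        *_, truth = small_study
        for (ct, region), markers in truth.planted_markers.items():
            lo, hi = small_config.marker_count_ranges[ct]
            assert lo <= len(markers) <= hi

    def test_endothelial_default_range_matches_atlas_report(self):
        assert DEFAULT_MARKER_RANGES["ENDO"] == (316, 473)


class TestBulkExperiment:
    def test_design_one_library_per_condition(self, small_study, small_config):
        _, bulk, *_ = small_study
        assert list(bulk.counts.columns) == [
            "CTRL_0h",
            "TNFA_4h",
            "TNFA_12h",
            "TNFA_36h",
            "IL1B_4h",
            "IL1B_12h",
            "IL1B_36h",
        ]
        assert bulk.control_sample == "CTRL_0h"
        lib = bulk.counts.sum(axis=0)
        assert ((lib / small_config.library_size - 1).abs() <= 0.10).all()

    def test_null_genes_have_stable_relative_abundance(self, small_study):
        # unplanted genes: fraction of the library is condition-independent,
        # so column-normalized counts agree within Poisson noise
        _, bulk, *_, truth = small_study
        null_genes = bulk.counts.index.difference(list(truth.planted_de))
        frac = bulk.counts.div(bulk.counts.sum(axis=0), axis=1)
        sub = frac.loc[null_genes]
        strong = sub["CTRL_0h"] > 2e-4
        ratio = sub.loc[strong].div(sub.loc[strong, "CTRL_0h"], axis=0)
        assert np.abs(np.log2(ratio.to_numpy())).max() < 0.5

    def test_planted_fold_changes_scale_expected_counts(self, small_study, small_config):
        # across planted genes the observed library-normalized ratio tracks
        # 2^planted_log2fc; the median multiplicative error stays near 1
        _, bulk, *_, truth = small_study
        frac = bulk.counts.div(bulk.counts.sum(axis=0), axis=1)
        errors = []
        for gene, per_cyt in truth.planted_de.items():
            for cytokine, spec in per_cyt.items():
                for tp, fc in spec["log2fc"].items():
                    obs = frac.loc[gene, f"{cytokine}_{tp}h"] / frac.loc[gene, "CTRL_0h"]
                    errors.append(obs / 2.0**fc)
        med = float(np.median(errors))
        assert med == pytest.approx(1.0, abs=0.1)

    def test_determinism(self, small_config):
        ref, truth = generate_reference_profiles(small_config)
        b1, t1 = generate_bulk_experiment(small_config, ref, GroundTruth(planted_markers=truth.planted_markers))
        b2, t2 = generate_bulk_experiment(small_config, ref, GroundTruth(planted_markers=truth.planted_markers))
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        assert t1.planted_de == t2.planted_de

    def test_null_calibration_without_planted_degs(self):
        # no planted responses: at FDR <= 0.001 and FC >= 2 essentially no
        # gene should be called differential
        frac_called = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_genes=3000,
                library_size=1_500_000,
                n_planted_de_per_pattern=0,
                n_cytokine_specific=0,
                marker_count_ranges={ct: (5, 10) for ct in SimulationConfig().cell_types},
                seed=100 + seed,
            )
            ref, truth = generate_reference_profiles(cfg)
            bulk, truth = generate_bulk_experiment(cfg, ref, truth)
            x = bulk.counts["CTRL_0h"].to_numpy()
            y = bulk.counts["TNFA_4h"].to_numpy()
            tested = (x > 0) | (y > 0)
            p = poisson_pair_pvalue(x[tested], y[tested], x.sum(), y.sum())
            fdr = bh_fdr(p)
            scale = np.sqrt(float(x.sum()) * y.sum())
            log2fc = np.log2((y[tested] * scale / y.sum() + 1) / (x[tested] * scale / x.sum() + 1))
            frac_called.append(((fdr <= 0.001) & (np.abs(log2fc) >= 1)).mean())
        assert np.mean(frac_called) <= 0.005


class TestQPCRPlate:
    def _truth(self):
        truth = GroundTruth()
        truth.planted_de["GENE_UP"] = {
            "TNFA": {"pattern": ("SU", "SU", "SU"), "log2fc": {4: 3.0, 12: 3.0, 36: 3.0}}
        }
        return truth

    def test_noise_free_delta_ct(self):
        cfg = SimulationConfig(seed=2, qpcr_noise_sd=0.0)
        truth = self._truth()
        plate = generate_qpcr_plate(truth, ["GENE_UP", "GAPDH", "YWHAZ"], cfg, noise_sd=0.0)
        eff = truth.qpcr_efficiencies["GENE_UP"]
        ct = plate[plate["primer"] == "GENE_UP"].groupby("condition")["ct"].mean()
        # abundance ratio 8 at efficiency eff: delta-ct = -3 / log2(eff)
        assert ct["TNFA_4h"] - ct["CTRL_0h"] == pytest.approx(-3.0 / np.log2(eff), rel=1e-12)

    def test_reference_genes_constant_in_expectation(self):
        cfg = SimulationConfig(seed=2)
        plate = generate_qpcr_plate(self._truth(), ["GENE_UP", "GAPDH", "YWHAZ"], cfg, noise_sd=0.0)
        for ref_gene in ("GAPDH", "YWHAZ"):
            cts = plate[plate["primer"] == ref_gene]["ct"]
            assert cts.nunique() == 1

    def test_missing_reference_genes_rejected(self):
        cfg = SimulationConfig(seed=2)
        with pytest.raises(ValueError, match="reference genes"):
            generate_qpcr_plate(self._truth(), ["GENE_UP", "GAPDH"], cfg)

    def test_round_trip_correlation(self, small_study, small_config):
        *_, plate, truth = small_study
        fc = analyze_plate(plate)
        planted = []
        measured = []
        for gene in fc.index:
            for col in fc.columns:
                cytokine, tp = col[:-1].rsplit("_", 1)
                spec = truth.planted_de.get(gene, {}).get(cytokine)
                planted.append(spec["log2fc"].get(int(tp), 0.0) if spec else 0.0)
                measured.append(fc.loc[gene, col])
        r = np.corrcoef(planted, measured)[0, 1]
        assert r > 0.9


def test_full_study_determinism(small_config):
    s1 = simulate_study(small_config)
    s2 = simulate_study(small_config)
    pd.testing.assert_frame_equal(s1[1].counts, s2[1].counts)
    pd.testing.assert_frame_equal(s1[4], s2[4])
    assert s1[2].sets == s2[2].sets
    assert s1[5].qpcr_efficiencies == s2[5].qpcr_efficiencies
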