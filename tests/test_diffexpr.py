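"""Two-library Poisson test, FPKM, FDR and DEG set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spheroseq.diffexpr import (
    bh_fdr,
    call_degs,
    common_degs,
    compute_fpkm,
    cytokine_specific_degs,
    poisson_pair_pvalue,
    shared_fraction,
    two_library_contrast,
)

from oracles import poisson_pair_pvalue_oracle


class TestFPKM:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 500], index=["g1", "g2"])
        fpkm = compute_fpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        assert fpkm.loc["g1", "s"] == pytest.approx(10.0)
        assert fpkm.loc["g2", "s"] == 0.0

    def test_matches_hand_formula_on_small_table(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(5, 2)), index=list("abcde"), columns=["s1", "s2"]
        )
        lengths = pd.Series(rng.integers(200, 5000, size=5), index=list("abcde"))
        fpkm = compute_fpkm(counts, lengths)
        lib = counts.sum(axis=0)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * lib[s])
                assert fpkm.loc[g, s] == pytest.approx(expected, rel=1e-12)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(counts, pd.Series({"g": 100}), pd.Series({"s": 0}))


class TestPoissonPairPvalue:
    def test_no_counts_no_evidence(self):
        assert poisson_pair_pvalue(0, 0, 1e6, 1e6) == 1.0

    def test_balanced_counts_equal_depth(self):
        # both inclusive tails exceed 0.5, so the doubled minimum caps at 1
        assert poisson_pair_pvalue(5, 5, 1e6, 1e6) == 1.0

    @pytest.mark.parametrize("x,y,n1,n2", [(10, 0, 1000, 1000), (10, 0, 1000, 2000), (3, 17, 2000, 1000)])
    def test_matches_summation_oracle(self, x, y, n1, n2):
        assert poisson_pair_pvalue(x, y, n1, n2) == pytest.approx(
            poisson_pair_pvalue_oracle(x, y, n1, n2), rel=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_pair_pvalue(-1, 2, 1e6, 1e6)

    @given(
        x=st.integers(0, 80),
        y=st.integers(0, 80),
        ratio=st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0]),
    )
    def test_symmetry_under_library_swap(self, x, y, ratio):
        n1, n2 = 1e6, 1e6 * ratio
        assert poisson_pair_pvalue(x, y, n1, n2) == pytest.approx(
            poisson_pair_pvalue(y, x, n2, n1), rel=1e-9
        )

    def test_monotone_in_count_divergence(self):
        x = 20
        ys = np.arange(20, 80)
        p = poisson_pair_pvalue(np.full_like(ys, x), ys, 1e6, 1e6)
        assert np.all(np.diff(p) <= 1e-15)
        ys_down = np.arange(20, -1, -1)
        p_down = poisson_pair_pvalue(np.full_like(ys_down, x), ys_down, 1e6, 1e6)
        assert np.all(np.diff(p_down) <= 1e-15)


class TestBHFDR:
    def test_hand_computed_example(self):
        # m=3: adjusted = min over j>=i of p_(j)*m/j -> (0.03, 0.03, 0.03)
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


def _contrast_frame(rows):
    df = pd.DataFrame(rows, columns=["log2fc", "fdr"])
    df.index = [f"g{i}" for i in range(len(rows))]
    return df


class TestCallDegs:
    def test_inclusive_boundaries(self):
        # FC exactly 2.00 and FDR exactly 0.001 both pass ("equal to or ...")
        degs = call_degs(_contrast_frame([(1.0, 0.001)]))
        assert list(degs.items()) == [("g0", "up")]

    def test_fold_change_gate(self):
        assert call_degs(_contrast_frame([(0.9, 1e-9)])).empty

    def test_downregulated(self):
        degs = call_degs(_contrast_frame([(-3.0, 0.0005)]))
        assert list(degs.items()) == [("g0", "down")]


def _cat(**kwargs):
    return {k: pd.Series("up", index=list(v)) for k, v in kwargs.items()}


class TestDegSetAlgebra:
    def test_common_requires_both_cytokines(self):
        catalog = {
            ("TNFA", 4): pd.Series("up", index=["a", "b"]),
            ("TNFA", 36): pd.Series("up", index=["c"]),
            ("IL1B", 12): pd.Series("up", index=["c", "d"]),
        }
        # in one TNFA list only -> excluded; TNFA 36 h + IL1B 12 h -> included
        assert common_degs(catalog) == {"c"}

    def test_common_empty_catalogs(self):
        catalog = {("TNFA", 4): pd.Series(dtype=object), ("IL1B", 4): pd.Series(dtype=object)}
        assert common_degs(catalog) == set()

    def test_common_missing_cytokine_errors(self):
        with pytest.raises(ValueError, match="IL1B"):
            common_degs({("TNFA", 4): pd.Series("up", index=["a"])})

    def test_cytokine_specific_strict_threshold(self):
        catalog = {
            ("TNFA", 4): pd.Series("up", index=["boundary", "strong", "shared"]),
            ("IL1B", 4): pd.Series("up", index=["shared"]),
        }
        profiles = {
            "TNFA": pd.DataFrame({4: [1.5, 2.2, 3.0]}, index=["boundary", "strong", "shared"]),
            "IL1B": pd.DataFrame({4: [0.0, 0.0, 3.0]}, index=["boundary", "strong", "shared"]),
        }
        cat_a, cat_b = cytokine_specific_degs(catalog, profiles)
        assert cat_a == {"strong"}  # |log2FC| = 1.5 exactly is excluded (strict)
        assert cat_b == set()  # shared gene lands in neither category

    def test_shared_fraction_arithmetic(self):
        catalog = {
            ("TNFA", 4): pd.Series("up", index=[f"g{i}" for i in range(100)]),
            ("IL1B", 4): pd.Series("up", index=[f"g{i}" for i in range(75, 125)]),
        }
        assert shared_fraction(catalog, 4) == (25, 50)

    def test_shared_fraction_identical_and_disjoint(self):
        same = {("TNFA", 4): pd.Series("up", index=["a"]), ("IL1B", 4): pd.Series("up", index=["a"])}
        assert shared_fraction(same, 4) == (100, 100)
        disjoint = {("TNFA", 4): pd.Series("up", index=["a"]), ("IL1B", 4): pd.Series("up", index=["b"])}
        assert shared_fraction(disjoint, 4) == (0, 0)


class TestTwoLibraryContrast:
    def test_untestable_genes_excluded_and_direction(self):
        counts = pd.DataFrame(
            {"CTRL_0h": [100, 0, 0, 50], "TNFA_4h": [100, 0, 80, 10]},
            index=["flat", "silent", "induced", "repressed"],
        )
        table = two_library_contrast(counts, "CTRL_0h", "TNFA_4h")
        assert "silent" not in table.index
        assert table.loc["induced", "direction"] == "up"
        assert table.loc["repressed", "direction"] == "down"
        assert table.loc["induced", "pvalue"] < table.loc["flat", "pvalue"]

    def test_equal_depth_log2fc_reduces_to_pseudocount_ratio(self):
        counts = pd.DataFrame({"a": [31, 169], "b": [63, 137]}, index=["g1", "g2"])
        # equal library sizes: log2fc = log2((y+1)/(x+1))
        n1, n2 = counts["a"].sum(), counts["b"].sum()
        assert n1 == n2
        table = two_library_contrast(counts, "a", "b")
        assert table.loc["g1", "log2fc"] == pytest.approx(1.0)
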