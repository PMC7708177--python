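"""D/A statistic, five-way classification, tallies and family tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteromir.datasets import (
    DIRECTION_COUNTS,
    HYBRIDS,
    load_printed_patterns,
    reconstruct_scaled_sets,
)
from heteromir.expression import tpm_normalize
from heteromir.heterosis import (
    ABSENT_MARKER,
    CATEGORIES,
    classify_da,
    classify_triad_table,
    compute_da,
    cross_hybrid_overlap,
    direction_of,
    family_of,
    family_pattern_table,
    tally_direction,
)


class TestComputeDA:
    @pytest.mark.parametrize(
        "f1,p1,p2,expected",
        [
            (20.0, 10.0, 20.0, 1.0),  # F1 equals the high parent
            (15.0, 10.0, 20.0, 0.0),  # F1 equals the mid-parent
            (30.0, 10.0, 20.0, 3.0),  # (30-15)/(20-15)
            (5.0, 10.0, 20.0, -2.0),
        ],
    )
    def test_direct_evaluation(self, f1, p1, p2, expected):
        assert compute_da(f1, p1, p2) == pytest.approx(expected)

    def test_equal_parents_undefined(self):
        assert compute_da(15.0, 10.0, 10.0) is None

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_da(10.0, -1.0, 20.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compute_da(float("nan"), 1.0, 2.0)

    @given(
        f1=st.floats(0, 1e4),
        p1=st.floats(0, 1e4),
        p2=st.floats(0, 1e4),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance_and_parent_symmetry(self, f1, p1, p2, k):
        base = compute_da(f1, p1, p2)
        scaled = compute_da(k * f1, k * p1, k * p2)
        swapped = compute_da(f1, p2, p1)
        if base is None:
            # degeneracy depends only on the parents, which scaling preserves
            assert swapped is None
        else:
            assert swapped == pytest.approx(base, rel=1e-9)
            if scaled is not None:
                assert scaled == pytest.approx(base, rel=1e-6)


class TestClassifyDA:
    @pytest.mark.parametrize(
        "da,category",
        [
            (8.36, "++"),
            (2.69, "++"),
            (-5.36, "--"),
            (-2.14, "--"),
            (0.41, "+-"),
            (0.51, "+"),
            (-0.6, "-"),
            (1.9, "+"),
            # boundaries go to the less extreme class
            (2.0, "+"),
            (0.5, "+-"),
            (-0.5, "+-"),
            (-2.0, "-"),
            (0.0, "+-"),
        ],
    )
    def test_examples_and_boundaries(self, da, category):
        assert classify_da(da) == category

    def test_undefined_passes_through(self):
        assert classify_da(None) == "undefined"
        assert classify_da(float("nan")) == "undefined"

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=300, derandomize=True)
    def test_monotone_in_da(self, x, y):
        lo, hi = sorted([x, y])
        assert CATEGORIES.index(classify_da(lo)) <= CATEGORIES.index(classify_da(hi))

    def test_printed_cells_reproduced(self):
        """Every printed (D/A, category) cell classifies to its printed label."""
        patterns = load_printed_patterns()
        for _, row in patterns.iterrows():
            assert classify_da(row["da"]) == row["category"], (
                row["mirna_id"],
                row["hybrid"],
                row["da"],
            )


class TestTallyDirection:
    def test_study_percentages(self):
        # per-hybrid induced/repressed counts give 60/54/54/55% repressed
        expected_pct = {"Zhengdan 958": 60, "Anyu 5": 54,
                        "Ye 478 x Huangzaosi": 54, "Zheng 58 x Huangzaosi": 55}
        for hybrid, (n_ind, n_rep) in DIRECTION_COUNTS.items():
            das = [1.0] * n_ind + [-1.0] * n_rep
            tally = tally_direction(das)
            assert tally.n_induced == n_ind
            assert tally.n_repressed == n_rep
            assert tally.percent_repressed == expected_pct[hybrid]

    def test_zero_and_undefined_excluded(self):
        tally = tally_direction([1.0, -1.0, 0.0, None])
        assert (tally.n_induced, tally.n_repressed) == (1, 1)
        assert tally.n_neutral == 1 and tally.n_undefined == 1
        assert tally.percent_repressed == 50

    def test_all_induced(self):
        assert tally_direction([0.3, 2.0, 5.0]).percent_repressed == 0

    def test_empty(self):
        tally = tally_direction([])
        assert tally.n_induced == 0 and tally.percent_repressed is None

    def test_direction_sign_convention(self):
        assert direction_of(0.01) == "induced"
        assert direction_of(-0.01) == "repressed"
        assert direction_of(0.0) == "neutral"
        assert direction_of(None) == "undefined"


class TestCrossHybridOverlap:
    def test_identical_sets(self):
        sets = {t: {"a", "b", "c"} for t in ("t1", "t2", "t3", "t4")}
        regions = cross_hybrid_overlap(sets)
        assert regions[("t1", "t2", "t3", "t4")] == 3
        assert sum(regions.values()) == 3

    def test_disjoint_sets(self):
        sets = {"t1": {"a"}, "t2": {"b", "c"}, "t3": {"d"}}
        regions = cross_hybrid_overlap(sets)
        assert regions[("t1",)] == 1 and regions[("t2",)] == 2 and regions[("t3",)] == 1
        assert regions[("t1", "t2", "t3")] == 0

    def test_regions_partition_the_union(self):
        sets = reconstruct_scaled_sets()
        regions = cross_hybrid_overlap(sets)
        assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            cross_hybrid_overlap({"t1": {"a"}})


class TestFamilyTables:
    def test_family_parsing(self):
        assert family_of("zma-miR156a-5p") == "miR156"
        assert family_of("zma-miR1432-5p") == "miR1432"
        assert family_of("novel-x") == "novel-x"

    def test_printed_mir156_row(self):
        """zma-miR156j-3p: absent in Zhengdan 958; --, -, -- elsewhere."""
        patterns = load_printed_patterns()
        fam = patterns[patterns["table"] == "miR156"]
        classifications = {
            hybrid: fam[fam["hybrid"] == hybrid].rename(columns={"mirna_id": "mirna"})
            for hybrid in HYBRIDS
        }
        table = family_pattern_table(classifications, "miR156")
        row = table.loc["zma-miR156j-3p"]
        assert row["Zhengdan 958"] == ABSENT_MARKER
        assert row["Anyu 5"] == (-3.19, "--")
        assert row["Zheng 58 x Huangzaosi"] == (-1.61, "-")
        assert row["Ye 478 x Huangzaosi"] == (-5.11, "--")
        # members never scaled in any triad do not appear
        assert "zma-miR399d-5p" not in table.index

    def test_planted_truth_recovered(self, noise_free_triad):
        counts, design, truth = noise_free_triad
        tpm = tpm_normalize(counts)
        table = classify_triad_table(
            tpm,
            design.samples("triad1", "hybrid"),
            design.samples("triad1", "maternal"),
            design.samples("triad1", "paternal"),
            "triad1",
            mirnas=truth["mirna"],
        )
        merged = table.merge(truth, on="mirna", suffixes=("_est", "_true"))
        assert (merged["category_est"] == merged["category_true"]).all()
        assert np.allclose(merged["da_est"], merged["da_true"], atol=1e-9)
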