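"""Hypergeometric enrichment, 2^-ddCt and Fisher's LSD letters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteromir.enrichment import delta_delta_ct, hypergeometric_enrichment, lsd_groups
from heteromir.synthetic import simulate_qpcr_cts


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets (N <= 12)."""
    universe = range(N)
    annotated = set(range(K))
    hits = sum(
        1 for subset in itertools.combinations(universe, n) if len(annotated & set(subset)) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeometricEnrichment:
    @staticmethod
    def build(N, K, n, k):
        background = [f"g{i}" for i in range(N)]
        annotation = {f"g{i}": ["T"] for i in range(K)}
        # target: k annotated genes + (n-k) unannotated ones
        target = [f"g{i}" for i in range(k)] + [f"g{i}" for i in range(K, K + n - k)]
        return target, background, annotation

    def test_term_covering_background_p_one(self):
        target, background, _ = self.build(10, 10, 4, 4)
        annotation = {g: ["T"] for g in background}
        res = hypergeometric_enrichment(target, background, annotation)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_frozen_enumeration_example(self):
        """N=10, K=5, n=4, k=4 -> p = 5/210, verified by subset enumeration."""
        target, background, annotation = self.build(10, 5, 4, 4)
        res = hypergeometric_enrichment(target, background, annotation)
        assert res.loc[0, "p_value"] == pytest.approx(5 / 210, rel=1e-12)
        assert res.loc[0, "p_value"] == pytest.approx(brute_force_upper_tail(10, 5, 4, 4))
        assert bool(res.loc[0, "significant"])

    @pytest.mark.parametrize(
        "N,K,n,k", [(8, 3, 4, 2), (10, 5, 4, 2), (12, 6, 5, 3), (9, 4, 3, 1), (12, 2, 6, 2)]
    )
    def test_matches_exhaustive_enumeration(self, N, K, n, k):
        target, background, annotation = self.build(N, K, n, k)
        res = hypergeometric_enrichment(target, background, annotation)
        assert res.loc[0, "k"] == k and res.loc[0, "K"] == K
        assert res.loc[0, "p_value"] == pytest.approx(
            brute_force_upper_tail(N, K, n, k), rel=1e-12
        )

    def test_empty_target_no_results(self):
        res = hypergeometric_enrichment([], [f"g{i}" for i in range(5)], {"g0": ["T"]})
        assert res.empty

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError, match="gX"):
            hypergeometric_enrichment(["gX"], ["g0"], {"g0": ["T"]})


class TestDeltaDeltaCt:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "replicate", "target_ct", "reference_ct"])

    def test_calibrator_fold_one(self):
        ct = self.make_table([("cal", 1, 25.0, 18.0), ("cal", 2, 25.2, 18.2)])
        rel = delta_delta_ct(ct, "cal")
        assert rel.loc[0, "delta_delta_ct"] == 0.0
        assert rel.loc[0, "fold_change"] == 1.0

    @pytest.mark.parametrize("ddct,fold", [(1.0, 0.5), (-2.0, 4.0), (0.0, 1.0)])
    def test_powers_of_two(self, ddct, fold):
        ct = self.make_table(
            [("cal", 1, 25.0, 18.0), ("s", 1, 25.0 + ddct, 18.0)]
        )
        rel = delta_delta_ct(ct, "cal").set_index("sample")
        assert rel.loc["s", "fold_change"] == pytest.approx(fold)

    def test_generator_inverse_fold_three(self):
        ct = simulate_qpcr_cts({"cal": 1.0, "s": 3.0}, noise_sd=0.0, n_reps=3, seed=0)
        rel = delta_delta_ct(ct, "cal").set_index("sample")
        assert rel.loc["s", "fold_change"] == pytest.approx(3.0, rel=1e-12)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_global_ct_shift(self, shift):
        ct = self.make_table(
            [("cal", 1, 25.0, 18.0), ("cal", 2, 24.8, 17.9), ("s", 1, 23.0, 18.1), ("s", 2, 23.3, 18.0)]
        )
        base = delta_delta_ct(ct, "cal")
        shifted_ct = ct.assign(
            target_ct=ct["target_ct"] + shift, reference_ct=ct["reference_ct"] + shift
        )
        shifted = delta_delta_ct(shifted_ct, "cal")
        assert np.allclose(base["fold_change"], shifted["fold_change"])

    def test_missing_reference_rejected(self):
        ct = self.make_table([("cal", 1, 25.0, 18.0), ("s", 1, 23.0, np.nan)])
        with pytest.raises(ValueError, match="missing Ct"):
            delta_delta_ct(ct, "cal")

    def test_unknown_calibrator_rejected(self):
        ct = self.make_table([("s", 1, 23.0, 18.0)])
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct(ct, "nope")


class TestLsdGroups:
    def test_identical_groups_share_a_letter(self):
        letters = lsd_groups({"a": [5.0, 5.1], "b": [5.0, 5.1], "c": [5.05, 5.0]})
        assert len(set(letters.values())) == 1

    def test_two_separated_groups(self):
        letters = lsd_groups({"hi": [100.0, 100.1, 99.9], "lo": [1.0, 1.1, 0.9]})
        assert letters["hi"] == "a" and letters["lo"] == "b"

    def test_hand_computed_three_groups(self):
        """Frozen LSD oracle: MSE=0.01, df=6, LSD=0.1998 -> 10 vs 10.1 share
        a letter, 20 stands alone."""
        values = {
            "g1": [9.9, 10.0, 10.1],
            "g2": [10.0, 10.1, 10.2],
            "g3": [19.9, 20.0, 20.1],
        }
        letters = lsd_groups(values)
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] != letters["g1"]

    def test_letters_are_valid_clique_cover(self):
        """Every same-letter pair is non-significant and every significant
        pair shares no letter (checked against the LSD rule directly)."""
        rng = np.random.default_rng(0)
        values = {f"g{i}": list(10 + i * 0.8 + 0.3 * rng.standard_normal(3)) for i in range(5)}
        letters = lsd_groups(values)
        from scipy import stats as sps

        arrays = {g: np.asarray(v) for g, v in values.items()}
        dfe = sum(len(a) - 1 for a in arrays.values())
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / dfe
        tcrit = sps.t.ppf(0.975, dfe)
        for g1, g2 in itertools.combinations(values, 2):
            lsd = tcrit * math.sqrt(mse * (1 / 3 + 1 / 3))
            significant = abs(arrays[g1].mean() - arrays[g2].mean()) > lsd
            share = bool(set(letters[g1]) & set(letters[g2]))
            assert share == (not significant), (g1, g2, letters)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            lsd_groups({"a": [1.0, 2.0]})

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            lsd_groups({"a": [1.0], "b": [2.0, 3.0]})
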