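"""Generators: planted truth, determinism, noise-free limits, validation."""

import numpy as np
import pandas as pd
import pytest

from heteromir.degradome import map_degradome_reads
from heteromir.enrichment import delta_delta_ct
from heteromir.expression import tpm_normalize
from heteromir.heterosis import compute_da
from heteromir.synthetic import (
    PlantedSite,
    TriadSimConfig,
    make_transcript_with_site,
    simulate_degradome_library,
    simulate_qpcr_cts,
    simulate_srna_reads,
    simulate_triads,
)

MIRNA = "TGACAGAAGAGAGTGAGCAC"  # 20 nt


class TestSimulateTriads:
    def test_seed_determinism(self):
        cfg = TriadSimConfig(n_mirnas=80, dispersion=0.05, seed=5)
        c1, _, t1 = simulate_triads(cfg)
        c2, _, t2 = simulate_triads(cfg)
        assert c1.equals(c2)
        assert t1.equals(t2)

    def test_additive_noise_free_limit(self):
        """dispersion=0 and divergence=1 plant F1 exactly at the mid-parent."""
        cfg = TriadSimConfig(n_mirnas=40, dispersion=0.0, parent_divergence=1.0, seed=3)
        counts, design, truth = simulate_triads(cfg)
        assert np.allclose(truth["f1_mean"], (truth["p1_mean"] + truth["p2_mean"]) / 2)
        assert (truth["category"] == "undefined").all()
        f1 = counts[design.samples("triad1", "hybrid")].mean(axis=1)
        p1 = counts[design.samples("triad1", "maternal")].mean(axis=1)
        p2 = counts[design.samples("triad1", "paternal")].mean(axis=1)
        assert np.allclose(f1, (p1 + p2) / 2)

    def test_truth_internal_consistency(self, noisy_triad):
        """Planted F1 mean = MP + D/A (HP - MP) exactly."""
        _, _, truth = noisy_triad
        mp = (truth["p1_mean"] + truth["p2_mean"]) / 2
        hp = truth[["p1_mean", "p2_mean"]].max(axis=1)
        assert np.allclose(truth["f1_mean"], mp + truth["da"] * (hp - mp), rtol=1e-12)

    def test_round_trip_recovers_planted_da(self, noise_free_triad):
        counts, design, truth = noise_free_triad
        tpm = tpm_normalize(counts)
        f1 = tpm[design.samples("triad1", "hybrid")].mean(axis=1)
        p1 = tpm[design.samples("triad1", "maternal")].mean(axis=1)
        p2 = tpm[design.samples("triad1", "paternal")].mean(axis=1)
        for _, row in truth.iterrows():
            da = compute_da(f1[row["mirna"]], p1[row["mirna"]], p2[row["mirna"]])
            assert da == pytest.approx(row["da"], abs=1e-9)

    def test_sample_means_track_planted_means(self):
        """Monte-Carlo: per-genotype sample-mean TPMs sit on the planted
        means; at dispersion 0.05 the median relative deviation over
        well-expressed miRNAs stays under 10%."""
        cfg = TriadSimConfig(n_mirnas=1000, dispersion=0.05, n_replicates=3, seed=11)
        counts, design, truth = simulate_triads(cfg)
        tpm = tpm_normalize(counts)
        # planted means on the TPM scale share one pool total per construction
        pool = 1.2 * max(
            truth["p1_mean"].sum(), truth["p2_mean"].sum(), truth["f1_mean"].sum()
        )
        rel_errs = []
        for role, col in (("maternal", "p1_mean"), ("paternal", "p2_mean"), ("hybrid", "f1_mean")):
            observed = tpm[design.samples("triad1", role)].mean(axis=1)
            planted_tpm = truth.set_index("mirna")[col] * 1e6 / pool
            keep = planted_tpm >= 50
            rel_errs.append(
                np.abs(observed[keep.index][keep] - planted_tpm[keep]) / planted_tpm[keep]
            )
        assert np.median(np.concatenate(rel_errs)) < 0.10

    def test_class_mix_validation(self):
        cfg = TriadSimConfig(n_mirnas=10, class_mix={"++": 0.6, "--": 0.5})
        with pytest.raises(ValueError, match="class_mix"):
            simulate_triads(cfg)

    def test_mean_range_validation(self):
        cfg = TriadSimConfig(n_mirnas=10, parent_mean_range=(100.0, 10.0))
        with pytest.raises(ValueError, match="parent_mean_range"):
            simulate_triads(cfg)

    def test_replicate_validation(self):
        with pytest.raises(ValueError, match="n_replicates"):
            simulate_triads(TriadSimConfig(n_mirnas=10, n_replicates=1))


class TestSimulateSrnaReads:
    def test_degenerate_class_profile(self):
        reads, features, _ = simulate_srna_reads({21: 1.0}, {"rRNA": 1.0}, 50, seed=1)
        rrna = [f for f in features if f.ftype == "rRNA"]
        assert len(rrna) == 1
        for r in reads:
            assert r.start >= rrna[0].start and r.end <= rrna[0].end

    def test_degenerate_length_profile(self):
        reads, _, _ = simulate_srna_reads({21: 1.0}, {"miRNA": 1.0}, 30, seed=2)
        assert all(len(r.seq) == 21 for r in reads)

    def test_truth_counts_sum_to_n_reads(self):
        _, _, truth = simulate_srna_reads(
            {21: 0.5, 24: 0.5}, {"miRNA": 0.4, "unannotated": 0.6}, 500, seed=3
        )
        assert truth["count"].sum() == 500

    def test_length_fraction_within_binomial_bound(self):
        n = 10_000
        _, _, truth = simulate_srna_reads(
            {21: 0.3, 24: 0.7}, {"unannotated": 1.0}, n, seed=4
        )
        observed = truth.loc[truth["length"] == 21, "count"].sum() / n
        sd = (0.3 * 0.7 / n) ** 0.5
        assert abs(observed - 0.3) < 3 * sd

    def test_profile_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_srna_reads({21: 0.5}, {"miRNA": 1.0}, 10, seed=0)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="n_reads"):
            simulate_srna_reads({21: 1.0}, {"miRNA": 1.0}, 0, seed=0)


class TestSimulateDegradome:
    def test_planted_peak_only(self):
        transcript = make_transcript_with_site(MIRNA, 400, 200, seed=5)
        reads = simulate_degradome_library(
            {"tx1": transcript}, [PlantedSite(MIRNA, "tx1", 200, 50)], background_rate=0.0, seed=6
        )
        assert len(reads) == 50
        profiles, _ = map_degradome_reads(reads, {"tx1": transcript})
        assert profiles["tx1"][199] == 50
        assert profiles["tx1"].sum() == 50

    def test_seed_determinism(self):
        transcript = make_transcript_with_site(MIRNA, 300, 150, seed=7)
        args = ({"tx1": transcript}, [PlantedSite(MIRNA, "tx1", 150, 5)], 0.05, 8)
        assert simulate_degradome_library(*args) == simulate_degradome_library(*args)

    def test_position_out_of_range_rejected(self):
        transcript = make_transcript_with_site(MIRNA, 300, 150, seed=9)
        with pytest.raises(ValueError, match="out of range"):
            simulate_degradome_library(
                {"tx1": transcript}, [PlantedSite(MIRNA, "tx1", 999, 5)], 0.0, 0
            )

    def test_bad_duplex_rejected(self):
        # transcript with no complementary site for the miRNA
        rng = np.random.default_rng(0)
        transcript = "".join(rng.choice(list("ACGT"), size=300))
        with pytest.raises(ValueError, match="above the configured maximum"):
            simulate_degradome_library(
                {"tx1": transcript}, [PlantedSite(MIRNA, "tx1", 150, 5)], 0.0, 0
            )


class TestSimulateQpcr:
    def test_noise_free_inverse(self):
        folds = {"cal": 1.0, "low": 0.5, "high": 3.0}
        ct = simulate_qpcr_cts(folds, noise_sd=0.0, n_reps=3, seed=1)
        rel = delta_delta_ct(ct, "cal").set_index("sample")
        for sample, fold in folds.items():
            assert rel.loc[sample, "fold_change"] == pytest.approx(fold, rel=1e-12)

    def test_half_fold_gives_ddct_one(self):
        ct = simulate_qpcr_cts({"cal": 1.0, "s": 0.5}, noise_sd=0.0)
        rel = delta_delta_ct(ct, "cal").set_index("sample")
        assert rel.loc["s", "delta_delta_ct"] == pytest.approx(1.0)

    def test_noisy_recovery_within_propagated_error(self):
        true_fold = 3.0
        noise = 0.1
        n = 3
        ct = simulate_qpcr_cts({"cal": 1.0, "s": true_fold}, noise_sd=noise, n_reps=n, seed=2)
        rel = delta_delta_ct(ct, "cal").set_index("sample")
        err = abs(np.log2(rel.loc["s", "fold_change"]) - np.log2(true_fold))
        assert err < 3 * noise * (2 / n) ** 0.5

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_qpcr_cts({"s": 0.0})
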