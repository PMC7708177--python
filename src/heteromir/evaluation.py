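"""Benchmark measurements on printed study tables and synthetic truth.

Everything here recomputes a quantity from scratch by running the package —
classifying printed D/A values, redoing the union/tally/Venn arithmetic
from published counts, and measuring recovery rates on simulations with
planted truth.  Used by the acceptance checks and the analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DE_COUNTS, DIRECTION_COUNTS, HYBRIDS, load_printed_patterns, reconstruct_scaled_sets
from .degradome import call_cleavage_sites, map_degradome_reads
from .expression import differential_test, scaled_union, tpm_normalize
from .heterosis import (
    classify_da,
    classify_triad_table,
    cross_hybrid_overlap,
    tally_direction,
)
from .synthetic import (
    PlantedSite,
    TriadSimConfig,
    make_transcript_with_site,
    simulate_degradome_library,
    simulate_triads,
)

DA_BOUNDARIES = (-2.0, -0.5, 0.5, 2.0)


def printed_pattern_concordance() -> tuple[int, int]:
    """(matching cells, total cells) when classify_da is applied to every
    printed (D/A, category) cell of the study's pattern tables."""
    patterns = load_printed_patterns()
    matches = sum(
        classify_da(row["da"]) == row["category"] for _, row in patterns.iterrows()
    )
    return matches, len(patterns)


def union_sizes_from_printed_counts() -> dict[str, int]:
    """Scaled-union size per hybrid, recomputed by set arithmetic from the
    printed per-side DE counts and overlaps (ID lists constructed to match
    the printed |A|, |B|, |A&B|)."""
    sizes = {}
    for hybrid, (n_a, n_b, n_common) in DE_COUNTS.items():
        common = [f"c{i}" for i in range(n_common)]
        a = common + [f"a{i}" for i in range(n_a - n_common)]
        b = common + [f"b{i}" for i in range(n_b - n_common)]
        sizes[hybrid] = scaled_union(a, b).n_union
    return sizes


def percent_repressed_from_printed_counts() -> dict[str, int]:
    """Percent repressed per hybrid via tally_direction on D/A sign lists
    matching the printed induced/repressed counts."""
    out = {}
    for hybrid, (n_induced, n_repressed) in DIRECTION_COUNTS.items():
        das = [1.0] * n_induced + [-1.0] * n_repressed
        out[hybrid] = tally_direction(das).percent_repressed
    return out


def venn_from_reconstruction() -> tuple[int, dict[str, int]]:
    """(all-four overlap, unique counts) computed by cross_hybrid_overlap on
    the reconstructed scaled ID sets."""
    sets = reconstruct_scaled_sets()
    regions = cross_hybrid_overlap(sets)
    common = regions[tuple(sorted(HYBRIDS))]
    uniques = {h: regions[(h,)] for h in HYBRIDS}
    return common, uniques


# ---------------------------------------------------------------------------
# simulation-based recovery measurements


@dataclass
class DARecovery:
    """Category-recovery summary on one simulated triad."""

    recovery: float  # fraction of eligible miRNAs whose class is recovered
    max_abs_error: float  # max |estimated - planted D/A| over eligible miRNAs
    n_eligible: int


def da_recovery(
    n_mirnas: int = 1000,
    dispersion: float = 0.05,
    seed: int = 0,
    min_parent_tpm: float = 100.0,
    boundary_margin: float = 0.25,
) -> DARecovery:
    """Classify a simulated triad through the full TPM -> D/A path and
    compare with the planted classes.

    Eligible miRNAs have both planted parent means >= ``min_parent_tpm``
    (TPM scale) and a planted D/A at least ``boundary_margin`` from every
    class boundary.
    """
    config = TriadSimConfig(n_mirnas=n_mirnas, dispersion=dispersion, seed=seed)
    counts, design, truth = simulate_triads(config)
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
    pool = 1.2 * max(truth["p1_mean"].sum(), truth["p2_mean"].sum(), truth["f1_mean"].sum())
    scale = 1e6 / pool  # planted means -> planted TPM
    margin = np.min(
        np.abs(merged["da_true"].to_numpy()[:, None] - np.array(DA_BOUNDARIES)), axis=1
    )
    eligible = (
        (merged[["p1_mean", "p2_mean"]].min(axis=1) * scale >= min_parent_tpm)
        & (margin >= boundary_margin)
    )
    sub = merged[eligible]
    return DARecovery(
        recovery=float((sub["category_est"] == sub["category_true"]).mean()),
        max_abs_error=float(np.max(np.abs(sub["da_est"] - sub["da_true"]))),
        n_eligible=int(len(sub)),
    )


def de_type1_rate(n_mirnas: int = 1000, seed: int = 0, ttest: str = "student") -> tuple[float, int]:
    """Fraction of miRNAs passing p < 0.01 alone under a pure null
    (parent_divergence 1: all nine samples share each miRNA's mean)."""
    config = TriadSimConfig(
        n_mirnas=n_mirnas, dispersion=0.05, parent_divergence=1.0, seed=seed
    )
    counts, design, truth = simulate_triads(config)
    tpm = tpm_normalize(counts)
    de = differential_test(
        tpm,
        design.samples("triad1", "hybrid"),
        design.samples("triad1", "maternal"),
        ttest=ttest,
    ).set_index("mirna")
    p = de.loc[truth["mirna"], "p_value"]
    return float((p < 0.01).mean()), int(len(p))


def de_power_4x(
    n_mirnas: int = 1000,
    seed: int = 0,
    min_parent_tpm: float = 100.0,
    min_fold: float = 4.0,
    ttest: str = "student",
) -> tuple[float, int]:
    """Detection power on hybrid-vs-parent contrasts whose planted fold
    change is >= ``min_fold`` (up or down) at parent mean >= 100 TPM."""
    config = TriadSimConfig(n_mirnas=n_mirnas, dispersion=0.05, seed=seed)
    counts, design, truth = simulate_triads(config)
    tpm = tpm_normalize(counts)
    pool = 1.2 * max(truth["p1_mean"].sum(), truth["p2_mean"].sum(), truth["f1_mean"].sum())
    scale = 1e6 / pool
    hyb = design.samples("triad1", "hybrid")
    n_detected = n_qualifying = 0
    for role, parent_col in (("maternal", "p1_mean"), ("paternal", "p2_mean")):
        de = differential_test(tpm, hyb, design.samples("triad1", role), ttest=ttest)
        de = de.set_index("mirna")
        parent = truth.set_index("mirna")[parent_col]
        f1 = truth.set_index("mirna")["f1_mean"]
        with np.errstate(divide="ignore"):
            fold = f1 / parent
        qualifying = (parent * scale >= min_parent_tpm) & (
            (fold >= min_fold) | (fold <= 1.0 / min_fold)
        )
        ids = qualifying[qualifying].index
        n_qualifying += len(ids)
        n_detected += int(de.loc[ids, "significant"].sum())
    return (n_detected / n_qualifying if n_qualifying else float("nan")), n_qualifying


@dataclass
class DegradomeRecovery:
    """Planted-site recovery over repeated simulated libraries."""

    n_planted: int
    n_recovered: int  # planted sites called at category 0, right spot, score 0
    n_false_category0: int  # category-0 calls at unplanted positions

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


MIRNA_PANEL = (
    "TGACAGAAGAGAGTGAGCAC",  # 20 nt
    "TTGGACTGAAGGGAGCTCCCT",  # 21 nt
    "TCGGACCAGGCTTCATTCCCC",  # 21 nt
)


def degradome_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    peak: int = 12,
    background_rate: float = 0.01,
) -> DegradomeRecovery:
    """Simulate ``n_seeds`` degradome libraries (one planted site per miRNA
    on its own transcript, plus an empty decoy transcript), call sites, and
    tally planted-site recovery at category 0 and false category-0 calls."""
    result = DegradomeRecovery(0, 0, 0)
    for i in range(n_seeds):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        transcripts: dict[str, str] = {}
        planted: list[PlantedSite] = []
        mirnas: dict[str, str] = {}
        for j, mseq in enumerate(MIRNA_PANEL):
            tid = f"tx{j}"
            pos = int(rng.integers(100, 300))
            transcripts[tid] = make_transcript_with_site(mseq, 450, pos, seed=seed * 10 + j)
            planted.append(PlantedSite(mseq, tid, pos, peak))
            mirnas[f"mir{j}"] = mseq
        transcripts["decoy"] = "".join(rng.choice(list("ACGT"), size=450))
        reads = simulate_degradome_library(
            transcripts, planted, background_rate=background_rate, seed=seed
        )
        profiles, _ = map_degradome_reads(reads, transcripts)
        sites = call_cleavage_sites(profiles, mirnas, transcripts)
        cat0 = sites[sites["category"] == 0]
        planted_keys = {(f"mir{j}", f"tx{j}", planted[j].cleavage_pos) for j in range(len(planted))}
        for site in planted:
            j = [p.transcript_id for p in planted].index(site.transcript_id)
            result.n_planted += 1
            hit = cat0[
                (cat0["mirna"] == f"mir{j}")
                & (cat0["transcript"] == site.transcript_id)
                & (cat0["position"] == site.cleavage_pos)
                & (cat0["score"] == 0.0)
            ]
            if len(hit) == 1:
                result.n_recovered += 1
        for _, row in cat0.iterrows():
            if (row["mirna"], row["transcript"], row["position"]) not in planted_keys:
                result.n_false_category0 += 1
    return result
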