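"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the study design of a maize hybrid/parent small-RNA
experiment: negative-binomial miRNA count triads with planted inheritance
modes, an sRNA read pool with a chosen length/annotation-class profile,
a degradome library with planted cleavage peaks, and qPCR Ct tables with
chosen fold changes.  Each generator is deterministic given its seed and
returns the truth it planted, so downstream estimators can be checked for
exact recovery in the noise-free limit and statistical recovery otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degradome import reverse_complement, score_duplex
from .heterosis import CATEGORIES, classify_da
from .io import Feature, TriadDesign

__all__ = [
    "CLASS_DA_INTERVALS",
    "TriadSimConfig",
    "simulate_triads",
    "SimulatedRead",
    "simulate_srna_reads",
    "PlantedSite",
    "make_transcript_with_site",
    "simulate_degradome_library",
    "simulate_qpcr_cts",
]

#: D/A sampling interval for each inheritance mode.  The outer classes are
#: truncated at +/-6 to keep planted values finite; sampling additionally
#: respects the F1 >= 0 feasibility bound (see simulate_triads).
CLASS_DA_INTERVALS: dict[str, tuple[float, float]] = {
    "++": (2.0, 6.0),
    "+": (0.5, 2.0),
    "+-": (-0.5, 0.5),
    "-": (-2.0, -0.5),
    "--": (-6.0, -2.0),
}

#: margin keeping sampled D/A off the class boundaries (dedicated boundary
#: behaviour is exercised by direct classify_da tests, not by simulation)
_BOUNDARY_MARGIN = 1e-6


@dataclass
class TriadSimConfig:
    """Configuration for one parent/parent/F1 count simulation.

    Parameters
    ----------
    n_mirnas
        Number of miRNAs to simulate.
    n_replicates
        Replicate libraries per genotype (3 in the emulated design; at least
        2 for any downstream t-test).
    class_mix
        Proportions over the five inheritance modes ("++", "+", "+-", "-",
        "--"); must sum to 1.
    parent_mean_range
        (low, high) of parental abundances on the TPM scale; base means are
        drawn log-uniformly, which mimics the strongly right-skewed miRNA
        abundance distributions of real libraries.
    parent_divergence
        Multiplicative factor >= 1 separating the two parental means.  With
        a factor of 1 the parents coincide, the additive half-range is zero
        and every planted D/A is undefined (a pure null for type-I checks).
    dispersion
        Negative-binomial dispersion alpha (variance = m + alpha * m^2);
        0 degenerates to exact deterministic means.
    library_size
        Expected total counts per sample.
    seed
        Seed for the generator.
    """

    n_mirnas: int
    n_replicates: int = 3
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"++": 0.15, "+": 0.15, "+-": 0.25, "-": 0.30, "--": 0.15}
    )
    parent_mean_range: tuple[float, float] = (20.0, 2000.0)
    parent_divergence: float = 2.0
    dispersion: float = 0.05
    library_size: int = 2_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas <= 0:
            raise ValueError("n_mirnas must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for downstream t-tests")
        if set(self.class_mix) - set(CATEGORIES):
            raise ValueError(
                f"class_mix has unknown classes: {sorted(set(self.class_mix) - set(CATEGORIES))}"
            )
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total!r})")
        lo, hi = self.parent_mean_range
        if not (0 < lo < hi) or not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("parent_mean_range must satisfy 0 < low < high and be finite")
        if self.parent_divergence < 1:
            raise ValueError("parent_divergence must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2.

    dispersion == 0 returns the exact means (floats): the noise-free limit
    must round-trip through TPM normalization and D/A computation exactly,
    which integer rounding would break.
    """
    if dispersion == 0:
        return mean.astype(float).copy()
    k = 1.0 / dispersion
    out = np.zeros_like(mean, dtype=float)
    pos = mean > 0
    out[pos] = rng.negative_binomial(k, k / (k + mean[pos]))
    return out


def simulate_triads(
    config: TriadSimConfig,
    triad: str = "triad1",
) -> tuple[pd.DataFrame, TriadDesign, pd.DataFrame]:
    """Simulate miRNA counts for one parent/parent/F1 triad.

    Per miRNA: a base abundance is drawn log-uniformly from
    ``parent_mean_range``; one parent (chosen at random) gets the base mean
    and the other gets base * divergence; an inheritance mode is drawn from
    ``class_mix`` and a D/A value uniformly from that mode's interval
    (truncated at +/-6 and at the bound keeping the implied F1 mean
    non-negative); the F1 mean is then MP + D/A * (HP - MP) exactly.
    Genotype mean vectors are scaled to ``library_size`` expected counts and
    replicates drawn negative-binomially.  A balancing "mirOTHER" row (the
    remainder of the small-RNA pool) gives every genotype the same planted
    total, so per-sample TPM normalization is a common rescale of the
    planted means and the planted D/A survives it exactly in the
    noise-free limit.

    Returns (counts, design, truth) where truth records the planted means,
    D/A and class per miRNA (class "undefined" when divergence == 1); the
    balancing row is present in counts but not in truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mirnas
    div = config.parent_divergence

    lo, hi = config.parent_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    p2_is_high = rng.random(n) < 0.5
    p1 = np.where(p2_is_high, base, base * div)
    p2 = np.where(p2_is_high, base * div, base)
    mp = (p1 + p2) / 2.0
    hp = np.maximum(p1, p2)

    if div == 1.0:
        da = np.full(n, np.nan)
        classes = np.array(["undefined"] * n, dtype=object)
        f1 = mp.copy()
    else:
        class_names = list(config.class_mix)
        probs = np.array([config.class_mix[c] for c in class_names], dtype=float)
        classes = rng.choice(np.array(class_names, dtype=object), size=n, p=probs / probs.sum())
        # F1 mean must stay non-negative: D/A >= -MP/(HP-MP) = -(1+div)/(div-1)
        feasible_lo = -(1.0 + div) / (div - 1.0)
        da = np.empty(n)
        for i, cls in enumerate(classes):
            c_lo, c_hi = CLASS_DA_INTERVALS[cls]
            lo_eff = max(c_lo, feasible_lo) + _BOUNDARY_MARGIN
            hi_eff = c_hi - _BOUNDARY_MARGIN
            if lo_eff >= hi_eff:
                raise ValueError(
                    f"class {cls!r} infeasible at parent_divergence={div}: "
                    f"D/A interval ({c_lo}, {c_hi}) lies below the F1>=0 bound {feasible_lo:.3g}"
                )
            da[i] = rng.uniform(lo_eff, hi_eff)
        f1 = mp + da * (hp - mp)

    mirnas = [f"mir{i + 1:05d}" for i in range(n)]
    # Close the composition: TPM divides each sample by its own total, so the
    # planted D/A only survives normalization if every genotype has the same
    # planted total.  A remainder row ("mirOTHER", the rest of the small-RNA
    # pool, excluded from the truth table) absorbs the difference.
    pool_total = 1.2 * max(p1.sum(), p2.sum(), f1.sum())
    genotype_means = {
        "P1": np.append(p1, pool_total - p1.sum()),
        "P2": np.append(p2, pool_total - p2.sum()),
        "F1": np.append(f1, pool_total - f1.sum()),
    }
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    role_of = {"P1": "maternal", "P2": "paternal", "F1": "hybrid"}
    for geno in ("P1", "P2", "F1"):
        means = genotype_means[geno]
        expected = means * (config.library_size / pool_total)
        for rep in range(1, config.n_replicates + 1):
            sample = f"{triad}_{geno}_rep{rep}"
            columns[sample] = _nb_sample(rng, expected, config.dispersion)
            design_rows.append(
                {"group": f"{triad}_{geno}", "role": role_of[geno], "triad": triad, "sample": sample}
            )

    counts = pd.DataFrame(columns, index=pd.Index(mirnas + ["mirOTHER"], name="mirna"))
    design = TriadDesign(pd.DataFrame(design_rows))
    truth = pd.DataFrame(
        {
            "mirna": mirnas,
            "p1_mean": p1,
            "p2_mean": p2,
            "f1_mean": f1,
            "da": da,
            "category": classes,
        }
    )
    return counts, design, truth


# ---------------------------------------------------------------------------
# sRNA read pool with genomic placements


@dataclass(frozen=True)
class SimulatedRead:
    """An sRNA read with its (known) genomic placement."""

    read_id: str
    seq: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    true_class: str


#: annotation classes a read can be planted into; exon/intron are split by
#: strand agreement between the read and the (plus-strand) feature
SRNA_CLASSES = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
)

_FEATURE_OF_CLASS = {
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat",
    "exon_sense": "exon",
    "exon_antisense": "exon",
    "intron_sense": "intron",
    "intron_antisense": "intron",
}

_BLOCK = 3000  # nt per feature block on the synthetic chromosome
_GAP = 500  # unannotated gap between blocks


def simulate_srna_reads(
    length_profile: Mapping[int, float],
    class_profile: Mapping[str, float],
    n_reads: int,
    seed: int = 0,
) -> tuple[list[SimulatedRead], list[Feature], pd.DataFrame]:
    """Generate an sRNA read pool over a synthetic annotated chromosome.

    One feature block per annotated class is laid out on a single synthetic
    chromosome, separated by unannotated gaps.  Each read draws a class from
    ``class_profile`` (keys from :data:`SRNA_CLASSES`), a length from
    ``length_profile`` (18-30 nt), and is placed uniformly inside a block of
    its class — on the plus strand, except antisense classes which go on the
    minus strand; "unannotated" reads land in a gap.  Sequences are random.

    Returns (reads, features, truth) where truth tabulates planted counts
    per class and per length (summing to ``n_reads``).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not length_profile or not class_profile:
        raise ValueError("length_profile and class_profile must be non-empty")
    for name, profile in (("length_profile", length_profile), ("class_profile", class_profile)):
        total = sum(profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {total!r})")
    bad = set(class_profile) - set(SRNA_CLASSES)
    if bad:
        raise ValueError(f"unknown annotation classes: {sorted(bad)}")
    bad_lens = [l for l in length_profile if not 18 <= l <= 30]
    if bad_lens:
        raise ValueError(f"read lengths outside 18-30 nt: {sorted(bad_lens)}")

    rng = np.random.default_rng(seed)
    chrom = "chrSim"

    # lay out one block per annotated feature class, in a fixed order
    features: list[Feature] = []
    block_of: dict[str, tuple[int, int]] = {}
    pos = _GAP
    for ftype in ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"):
        features.append(Feature(chrom, pos, pos + _BLOCK, "+", ftype, f"{ftype}_block"))
        block_of[ftype] = (pos, pos + _BLOCK)
        pos += _BLOCK + _GAP
    gap_start = pos  # trailing unannotated region
    gap_end = pos + _BLOCK

    class_names = list(class_profile)
    class_p = np.array([class_profile[c] for c in class_names], dtype=float)
    lens = np.array(sorted(length_profile))
    len_p = np.array([length_profile[l] for l in lens], dtype=float)

    chosen_cls = rng.choice(np.array(class_names, dtype=object), size=n_reads, p=class_p / class_p.sum())
    chosen_len = rng.choice(lens, size=n_reads, p=len_p / len_p.sum())

    alphabet = np.array(list("ACGT"))
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        cls = str(chosen_cls[i])
        length = int(chosen_len[i])
        if cls == "unannotated":
            lo_b, hi_b = gap_start, gap_end
            strand = "+"
        else:
            lo_b, hi_b = block_of[_FEATURE_OF_CLASS[cls]]
            strand = "-" if cls.endswith("antisense") else "+"
        start = int(rng.integers(lo_b, hi_b - length))
        seq = "".join(rng.choice(alphabet, size=length))
        reads.append(
            SimulatedRead(f"read{i + 1:06d}", seq, chrom, start, start + length, strand, cls)
        )

    truth = (
        pd.DataFrame({"true_class": chosen_cls, "length": chosen_len})
        .groupby(["true_class", "length"])
        .size()
        .rename("count")
        .reset_index()
    )
    return reads, features, truth


# ---------------------------------------------------------------------------
# degradome library


@dataclass(frozen=True)
class PlantedSite:
    """A planted miRNA-guided cleavage site on a transcript."""

    mirna_seq: str
    transcript_id: str
    cleavage_pos: int  # 1-based transcript position of the fragment 5' end
    peak_reads: int


def make_transcript_with_site(
    mirna_seq: str,
    length: int,
    cleavage_pos: int,
    seed: int = 0,
) -> str:
    """Random transcript carrying a perfect target site for ``mirna_seq``.

    The reverse complement of the miRNA is embedded so the transcript base
    paired to miRNA position 10 sits at ``cleavage_pos`` (1-based): the
    target window starts at cleavage_pos - (L - 10).
    """
    rng = np.random.default_rng(seed)
    L = len(mirna_seq)
    window_start = cleavage_pos - (L - 10)  # 1-based
    if window_start < 1 or window_start + L - 1 > length:
        raise ValueError(
            f"cleavage position {cleavage_pos} leaves no room for a {L}-nt site "
            f"in a {length}-nt transcript"
        )
    seq = list("".join(rng.choice(np.array(list("ACGT")), size=length)))
    site = reverse_complement(mirna_seq.upper().replace("U", "T"))
    seq[window_start - 1 : window_start - 1 + L] = list(site)
    return "".join(seq)


def simulate_degradome_library(
    transcripts: Mapping[str, str],
    planted_sites: Sequence[PlantedSite],
    background_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 20,
    max_score: float = 7.0,
) -> list[tuple[str, str]]:
    """Degradome reads (id, sequence) with planted 5'-end peaks.

    Each planted site contributes exactly ``peak_reads`` reads whose 5' end
    is the cleavage position; the site's target window must form a duplex
    with its miRNA scoring <= ``max_score``.  Background reads are drawn
    per transcript position as Poisson(``background_rate``), sense strand
    only (degradome sequencing captures 5' ends of sense cleavage
    fragments).  Deterministic given the seed.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    counter = 0

    for site in planted_sites:
        if site.transcript_id not in transcripts:
            raise ValueError(f"planted site on unknown transcript {site.transcript_id!r}")
        tseq = transcripts[site.transcript_id].upper().replace("U", "T")
        L = len(site.mirna_seq)
        pos = site.cleavage_pos
        if not 1 <= pos <= len(tseq):
            raise ValueError(
                f"cleavage position {pos} out of range for transcript "
                f"{site.transcript_id!r} (length {len(tseq)})"
            )
        window_start = pos - (L - 10)
        if window_start < 1 or window_start + L - 1 > len(tseq):
            raise ValueError(
                f"target window for cleavage position {pos} falls outside "
                f"transcript {site.transcript_id!r}"
            )
        window = tseq[window_start - 1 : window_start - 1 + L]
        score = score_duplex(site.mirna_seq, window)
        if score > max_score:
            raise ValueError(
                f"planted duplex on {site.transcript_id!r} at {pos} scores "
                f"{score}, above the configured maximum {max_score}"
            )
        frag = tseq[pos - 1 : pos - 1 + read_length]
        for _ in range(site.peak_reads):
            counter += 1
            reads.append((f"deg{counter:06d}", frag))

    if background_rate > 0:
        for tid in sorted(transcripts):
            tseq = transcripts[tid].upper().replace("U", "T")
            n_pos = max(len(tseq) - read_length + 1, 0)
            hits = rng.poisson(background_rate, size=n_pos)
            for p0 in np.nonzero(hits)[0]:
                frag = tseq[p0 : p0 + read_length]
                for _ in range(int(hits[p0])):
                    counter += 1
                    reads.append((f"deg{counter:06d}", frag))
    return reads


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_qpcr_cts(
    true_fold_changes: Mapping[str, float],
    reference_ct: float = 18.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    calibrator_delta_ct: float = 3.0,
) -> pd.DataFrame:
    """Ct table whose 2^-ddCt analysis recovers the chosen fold changes.

    Fold changes are relative to a calibrator sample with fold 1 (amplification
    efficiency fixed at 2 per cycle): the target Ct of a sample with fold f is
    reference_ct + calibrator_delta_ct - log2(f), plus Gaussian noise of
    ``noise_sd`` Ct units on the target Ct only.  With ``noise_sd`` = 0 the
    ddCt estimate inverts the model exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for sample, fold in true_fold_changes.items():
        if not (fold > 0 and math.isfinite(fold)):
            raise ValueError(f"fold change for sample {sample!r} must be positive, got {fold!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in true_fold_changes.items():
        base_ct = reference_ct + calibrator_delta_ct - math.log2(fold)
        for rep in range(1, n_reps + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "target_ct": base_ct + noise,
                    "reference_ct": reference_ct,
                }
            )
    return pd.DataFrame(rows)
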