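"""Degradome (PARE) cleavage-site calling for miRNA targets.

Degradome sequencing captures the 5' ends of uncapped mRNA fragments; a
miRNA-guided cleavage event leaves a fragment whose 5' end sits opposite
miRNA positions 10-11 of the miRNA:target duplex.  This module maps
degradome read 5' ends onto transcripts, scores candidate miRNA:target
duplexes with the standard plant penalty scheme (Watson-Crick 0, G:U wobble
0.5, mismatch 1, penalties doubled over the core, miRNA positions 2-13;
ungapped), and calls sites whose duplex score is within a maximum (default
7) together with a T-plot abundance category:

    0  site count is the transcript maximum and that maximum is unique
    1  site count equals a maximum reached at more than one position
    2  site count is below the maximum but above the median of the
       non-zero positions
    3  site count is at or below that median (and > 1 read)
    4  exactly one read at the site

A single read is always category 4, even when it happens to be the
transcript maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "reverse_complement",
    "map_degradome_reads",
    "score_duplex",
    "call_cleavage_sites",
    "tplot_table",
    "MappingStats",
]

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

#: Watson-Crick pairs as (miRNA base, target base), DNA alphabet
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
#: G:U wobble pairs: miRNA G pairs target U(T), miRNA U(T) pairs target G
_WOBBLE = {("G", "T"), ("T", "G")}


def reverse_complement(seq: str) -> str:
    """Reverse complement in DNA letters (U treated as T)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def score_duplex(mirna: str, target_site: str) -> float:
    """Penalty score of the antiparallel miRNA:target duplex (ungapped).

    ``mirna`` and ``target_site`` are both 5'->3' and must have equal
    length; miRNA position i (1-based) pairs with target-site position
    L - i + 1.  Watson-Crick 0, G:U wobble 0.5, mismatch 1; penalties are
    doubled at miRNA positions 2-13 (the core around the cleavage site).
    """
    m = _norm(mirna)
    t = _norm(target_site)
    if len(m) != len(t):
        raise ValueError(
            f"duplex sequences must have equal length (miRNA {len(m)}, window {len(t)})"
        )
    L = len(m)
    score = 0.0
    for i in range(1, L + 1):
        pair = (m[i - 1], t[L - i])
        if pair in _WC:
            penalty = 0.0
        elif pair in _WOBBLE:
            penalty = 0.5
        else:
            penalty = 1.0
        if 2 <= i <= 13:
            penalty *= 2.0
        score += penalty
    return score


@dataclass
class MappingStats:
    """Bookkeeping for one degradome mapping run."""

    n_reads: int = 0
    n_mapped: int = 0  # reads with >= 1 hit
    n_unmapped: int = 0
    n_multi: int = 0  # reads hitting more than one location
    n_hits: int = 0  # total profile increments (multi-hits counted per hit)


def map_degradome_reads(
    reads: Iterable[tuple[str, str]],
    transcripts: Mapping[str, str],
    prefix_length: int = 20,
    min_length: int = 15,
) -> tuple[dict[str, np.ndarray], MappingStats]:
    """Map degradome read 5' ends onto transcript positions.

    The first ``prefix_length`` nt of each read are matched as an exact
    substring against the sense strand of every transcript; every occurrence
    increments the profile at the position of the read's 5'-most base
    (profiles are 0-indexed arrays over 1-based transcript positions).
    Reads shorter than ``min_length`` after trimming are skipped and counted
    as unmapped.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    seqs = {tid: _norm(seq) for tid, seq in transcripts.items()}
    profiles = {tid: np.zeros(len(seq), dtype=int) for tid, seq in seqs.items()}
    stats = MappingStats()
    for _read_id, read_seq in reads:
        stats.n_reads += 1
        prefix = _norm(read_seq)[:prefix_length]
        if len(prefix) < min_length:
            stats.n_unmapped += 1
            continue
        hits = 0
        for tid, tseq in seqs.items():
            start = tseq.find(prefix)
            while start != -1:
                profiles[tid][start] += 1
                hits += 1
                start = tseq.find(prefix, start + 1)
        if hits == 0:
            stats.n_unmapped += 1
        else:
            stats.n_mapped += 1
            stats.n_hits += hits
            if hits > 1:
                stats.n_multi += 1
    return profiles, stats


def _site_category(count: int, profile: np.ndarray) -> int:
    """T-plot abundance category of a site with ``count`` reads."""
    if count == 1:
        return 4
    maximum = int(profile.max())
    at_max = int((profile == maximum).sum())
    if count == maximum:
        return 0 if at_max == 1 else 1
    nonzero = profile[profile > 0]
    median = float(np.median(nonzero))
    return 2 if count > median else 3


def call_cleavage_sites(
    profiles: Mapping[str, np.ndarray],
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_score: float = 7.0,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Call categorized cleavage sites for every miRNA x transcript pair.

    The miRNA is slid over every ungapped transcript window; windows whose
    duplex score is <= ``max_score`` nominate the transcript base paired to
    miRNA position 10 as the cleavage position (1-based).  A site is
    reported when the degradome profile carries >= ``min_reads`` reads
    there.  Returns a DataFrame with columns mirna, transcript, position,
    reads, score, category, sorted by (mirna, transcript, position).
    """
    rows = []
    for mirna_id in sorted(mirnas):
        mseq = _norm(mirnas[mirna_id])
        L = len(mseq)
        for tid in sorted(profiles):
            if tid not in transcripts:
                raise KeyError(f"profile for unknown transcript {tid!r}")
            tseq = _norm(transcripts[tid])
            profile = profiles[tid]
            for start0 in range(len(tseq) - L + 1):
                window = tseq[start0 : start0 + L]
                score = score_duplex(mseq, window)
                if score > max_score:
                    continue
                # miRNA position 10 pairs with window position L-10+1
                pos = start0 + (L - 10) + 1  # 1-based cleavage position
                count = int(profile[pos - 1])
                if count < min_reads or count == 0:
                    continue
                rows.append(
                    {
                        "mirna": mirna_id,
                        "transcript": tid,
                        "position": pos,
                        "reads": count,
                        "score": score,
                        "category": _site_category(count, profile),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["mirna", "transcript", "position", "reads", "score", "category"]
    )
    return df.sort_values(["mirna", "transcript", "position"], ignore_index=True)


def tplot_table(profile: np.ndarray, site_position: int | None = None) -> pd.DataFrame:
    """Per-position degradome counts for a transcript (T-plot data).

    Columns: position (1-based), count, is_site (marks the called cleavage
    position when given).
    """
    positions = np.arange(1, len(profile) + 1)
    return pd.DataFrame(
        {
            "position": positions,
            "count": profile.astype(int),
            "is_site": positions == site_position if site_position else False,
        }
    )
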