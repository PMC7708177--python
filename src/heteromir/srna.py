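"""sRNA read-set profiling: length distribution, annotation classes,
and exact matching against a mature-miRNA reference.

Reads are classified against stranded feature intervals into the flat
vocabulary used for small-RNA library summaries: miRNA, rRNA, tRNA, snRNA,
snoRNA, repeat, exon sense/antisense, intron sense/antisense, unannotated.
When a read overlaps features of several classes, a fixed precedence makes
the assignment deterministic: structural small-RNA annotations win over
genic context (miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon >
intron).  Exon and intron hits are split by strand agreement between the
read and the feature.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import Feature

__all__ = [
    "LengthHistogram",
    "length_distribution",
    "ReadClassSummary",
    "annotate_read_classes",
    "match_known_mirnas",
    "CLASS_PRECEDENCE",
    "SUMMARY_CLASSES",
]

MIN_LEN, MAX_LEN = 18, 30

#: feature-type precedence for multi-class reads (highest first)
CLASS_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")

#: output classes of the library summary, in report order
SUMMARY_CLASSES = (
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "miRNA",
    "rRNA",
    "repeat",
    "snRNA",
    "snoRNA",
    "tRNA",
    "unannotated",
)


@dataclass
class LengthHistogram:
    """Read counts per length over 18-30 nt plus an "other" bucket."""

    counts: dict[int, int]
    other: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.other

    def to_frame(self) -> pd.DataFrame:
        rows = [{"length": l, "count": self.counts.get(l, 0)} for l in range(MIN_LEN, MAX_LEN + 1)]
        rows.append({"length": "other", "count": self.other})
        return pd.DataFrame(rows)


def length_distribution(sequences: Iterable[str]) -> LengthHistogram:
    """Histogram of read lengths; lengths outside 18-30 nt go to "other"."""
    counts: Counter[int] = Counter()
    other = 0
    n = 0
    for seq in sequences:
        n += 1
        length = len(seq)
        if MIN_LEN <= length <= MAX_LEN:
            counts[length] += 1
        else:
            other += 1
    if n == 0:
        raise ValueError("length_distribution: empty read set")
    return LengthHistogram(counts=dict(counts), other=other)


@dataclass
class ReadClassSummary:
    """Per-class read counts and percentages for one library."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        return pd.DataFrame(
            [
                {
                    "class": cls,
                    "count": self.counts.get(cls, 0),
                    "percent": 100.0 * self.counts.get(cls, 0) / total if total else 0.0,
                }
                for cls in SUMMARY_CLASSES
            ]
        )


def annotate_read_classes(
    reads: Sequence, features: Iterable[Feature]
) -> ReadClassSummary:
    """Assign every placed read to exactly one annotation class.

    ``reads`` must carry chrom, start, end (0-based half-open) and strand
    attributes (e.g. :class:`~heteromir.synthetic.SimulatedRead`).  A read
    overlapping no feature is "unannotated"; otherwise the highest-
    precedence overlapping feature type wins and exon/intron are suffixed
    _sense/_antisense by strand agreement.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in features:
        trees[feat.chrom].addi(feat.start, feat.end, feat)

    rank = {ftype: i for i, ftype in enumerate(CLASS_PRECEDENCE)}
    counts: Counter[str] = Counter()
    for read in reads:
        hits = trees[read.chrom].overlap(read.start, read.end) if read.chrom in trees else ()
        best: Feature | None = None
        for hit in hits:
            feat = hit.data
            if feat.ftype not in rank:
                continue
            if best is None or rank[feat.ftype] < rank[best.ftype]:
                best = feat
        if best is None:
            counts["unannotated"] += 1
        elif best.ftype in ("exon", "intron"):
            suffix = "sense" if read.strand == best.strand else "antisense"
            counts[f"{best.ftype}_{suffix}"] += 1
        else:
            counts[best.ftype] += 1
    return ReadClassSummary(counts=dict(counts))


def match_known_mirnas(
    srna_sequences: Iterable[str],
    mature_reference: Mapping[str, str],
) -> pd.DataFrame:
    """Count sRNA reads matching mature miRNAs exactly over the full length.

    Only reads of 18-25 nt are considered (the conventional mature-miRNA
    matching window).  U/T spelling is normalized to T on both sides.  A
    read matching several mature sequences counts toward each, and those
    miRNAs are flagged multi_hit.  Returns a DataFrame with columns
    mirna_id, count, multi_hit covering every reference entry.
    """
    if not mature_reference:
        raise ValueError("mature miRNA reference is empty")
    seq_to_ids: dict[str, list[str]] = defaultdict(list)
    for mirna_id, seq in mature_reference.items():
        seq_to_ids[seq.upper().replace("U", "T")].append(mirna_id)

    counts: Counter[str] = Counter()
    multi: set[str] = set()
    for raw in srna_sequences:
        if not 18 <= len(raw) <= 25:
            continue
        seq = raw.upper().replace("U", "T")
        ids = seq_to_ids.get(seq, ())
        for mirna_id in ids:
            counts[mirna_id] += 1
            if len(ids) > 1:
                multi.add(mirna_id)
    return pd.DataFrame(
        [
            {"mirna_id": mid, "count": counts.get(mid, 0), "multi_hit": mid in multi}
            for mid in sorted(mature_reference)
        ]
    )
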