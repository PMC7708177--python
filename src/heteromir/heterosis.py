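"""Dominance/additivity (D/A) classification of hybrid miRNA expression.

For a parent/parent/F1 triad with replicate-mean abundances P1, P2 and F1
(TPM scale), the mid-parent value is MP = (P1 + P2)/2 and the high-parent
value is HP = max(P1, P2).  The D/A statistic

    D/A = (F1 - MP) / (HP - MP)

expresses the dominance deviation of the hybrid in units of the additive
half-range.  D/A = 0 is perfectly additive expression, D/A = 1 equals the
high parent, D/A = -1 equals the low parent, and values beyond +/-1 indicate
over/under-dominance.  Each miRNA is binned into one of five inheritance
modes:

    ++   extremely high parental   D/A > 2
    +    high parental             0.5 < D/A <= 2
    +-   additive                  -0.5 <= D/A <= 0.5
    -    low parental              -2 <= D/A < -0.5
    --   extremely low parental    D/A < -2

The published intervals are open at the four thresholds; boundary values are
assigned to the less extreme class.  D/A > 0 counts as "induced" in the
hybrid, D/A < 0 as "repressed".  When the two parents are (numerically)
indistinguishable the half-range vanishes and D/A is undefined.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "compute_da",
    "classify_da",
    "direction_of",
    "classify_triad_table",
    "DirectionTally",
    "tally_direction",
    "cross_hybrid_overlap",
    "family_of",
    "family_pattern_table",
    "ABSENT_MARKER",
]

#: five inheritance modes, ordered from most repressed to most induced
CATEGORIES = ("--", "-", "+-", "+", "++")

#: marker printed for a family member not scaled in a given triad
ABSENT_MARKER = "\\"


def compute_da(f1: float, p1: float, p2: float, epsilon: float = 1e-9) -> float | None:
    """D/A value (F1 - MP)/(HP - MP), or None when the denominator vanishes.

    Parameters
    ----------
    f1, p1, p2
        Replicate-mean abundances (TPM) of the hybrid and the two parents.
    epsilon
        Relative tolerance for the degenerate-parents test: the statistic is
        undefined when ``HP - MP < epsilon * max(1, HP)``.
    """
    for name, v in (("f1", f1), ("p1", p1), ("p2", p2)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    mp = (p1 + p2) / 2.0
    hp = max(p1, p2)
    if hp - mp < epsilon * max(1.0, hp):
        return None
    return (f1 - mp) / (hp - mp)


def classify_da(da: float | None) -> str:
    """Five-way inheritance mode for a D/A value.

    Thresholds at +/-0.5 and +/-2; exact boundary values go to the less
    extreme class (so 0.5 and -0.5 are additive, 2 is high parental and -2
    low parental).  ``None`` (undefined D/A) passes through as "undefined".
    """
    if da is None or (isinstance(da, float) and math.isnan(da)):
        return "undefined"
    if da > 2:
        return "++"
    if da > 0.5:
        return "+"
    if da >= -0.5:
        return "+-"
    if da >= -2:
        return "-"
    return "--"


def direction_of(da: float | None) -> str:
    """Induced (D/A > 0), repressed (D/A < 0), neutral (= 0) or undefined."""
    if da is None or (isinstance(da, float) and math.isnan(da)):
        return "undefined"
    if da > 0:
        return "induced"
    if da < 0:
        return "repressed"
    return "neutral"


def classify_triad_table(
    tpm: pd.DataFrame,
    hybrid_samples: Iterable[str],
    maternal_samples: Iterable[str],
    paternal_samples: Iterable[str],
    triad: str,
    mirnas: Iterable[str] | None = None,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Per-miRNA D/A classification table for one triad.

    Means are taken across replicate columns of ``tpm``; rows are restricted
    to ``mirnas`` (the scaled set) when given.  Returns a DataFrame with
    columns mirna, triad, f1, p1, p2, da, category, direction.
    """
    sub = tpm.loc[list(mirnas)] if mirnas is not None else tpm
    f1 = sub[list(hybrid_samples)].mean(axis=1)
    p1 = sub[list(maternal_samples)].mean(axis=1)
    p2 = sub[list(paternal_samples)].mean(axis=1)
    rows = []
    for mirna in sub.index:
        da = compute_da(float(f1[mirna]), float(p1[mirna]), float(p2[mirna]), epsilon)
        rows.append(
            {
                "mirna": mirna,
                "triad": triad,
                "f1": float(f1[mirna]),
                "p1": float(p1[mirna]),
                "p2": float(p2[mirna]),
                "da": np.nan if da is None else da,
                "category": classify_da(da),
                "direction": direction_of(da),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DirectionTally:
    """Induced/repressed tally for one triad's scaled miRNAs."""

    n_induced: int
    n_repressed: int
    n_neutral: int
    n_undefined: int
    percent_repressed: int | None

    @property
    def n_classified(self) -> int:
        return self.n_induced + self.n_repressed


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tally_direction(das: Iterable[float | None]) -> DirectionTally:
    """Count induced (D/A > 0) and repressed (D/A < 0) miRNAs.

    Exact zeros and undefined values are excluded from both counts and
    reported separately.  ``percent_repressed`` is 100 * repressed /
    (induced + repressed), rounded half-up to the nearest integer; it is
    None when nothing is classified.
    """
    counts = {"induced": 0, "repressed": 0, "neutral": 0, "undefined": 0}
    for da in das:
        counts[direction_of(da)] += 1
    denom = counts["induced"] + counts["repressed"]
    pct = _round_half_up(100.0 * counts["repressed"] / denom) if denom else None
    return DirectionTally(
        n_induced=counts["induced"],
        n_repressed=counts["repressed"],
        n_neutral=counts["neutral"],
        n_undefined=counts["undefined"],
        percent_repressed=pct,
    )


def cross_hybrid_overlap(
    scaled_sets: Mapping[str, set[str]],
) -> dict[tuple[str, ...], int]:
    """Venn partition of scaled-miRNA ID sets across triads.

    Returns the count of IDs in every exclusive region, keyed by the sorted
    tuple of triad names the region belongs to (all 2^k - 1 regions, zero
    counts included).  Region counts sum to the size of the overall union.
    """
    names = sorted(scaled_sets)
    if len(names) < 2:
        raise ValueError("cross_hybrid_overlap needs at least two triads")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(scaled_sets[n]) for n in combo))
            outside = set.union(
                *(set(scaled_sets[n]) for n in names if n not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return regions


_FAMILY_RE = re.compile(r"(miR)(\d+)", re.IGNORECASE)


def family_of(mirna_id: str) -> str:
    """miRNA family name from a miRBase-style ID.

    "zma-miR156a-5p" -> "miR156".  IDs without a recognisable family number
    map to themselves.
    """
    m = _FAMILY_RE.search(mirna_id)
    if m is None:
        return mirna_id
    return f"miR{m.group(2)}"


def family_pattern_table(
    classifications: Mapping[str, pd.DataFrame],
    family: str,
    family_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Family-level (D/A, category) matrix across triads.

    ``classifications`` maps triad name -> classification table (as produced
    by :func:`classify_triad_table`; needs columns mirna, da, category).
    Cells of members not scaled in a triad carry the absent marker "\\";
    members scaled in no triad are excluded.  Cell values are
    ``(da, category)`` tuples, formatted by :func:`format_family_table`.
    """
    triads = list(classifications)
    members: dict[str, dict[str, tuple[float, str] | str]] = {}
    for triad, table in classifications.items():
        for _, row in table.iterrows():
            fam = (
                family_map[row["mirna"]]
                if family_map is not None and row["mirna"] in family_map
                else family_of(row["mirna"])
            )
            if fam != family:
                continue
            members.setdefault(row["mirna"], {})[triad] = (
                float(row["da"]),
                row["category"],
            )
    out = pd.DataFrame(
        {
            triad: [members[m].get(triad, ABSENT_MARKER) for m in members]
            for triad in triads
        },
        index=pd.Index(sorted(members), name="mirna"),
    ).loc[sorted(members)]
    return out


def format_family_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Render a family table with 'da category' strings and "\\" for absent."""

    def fmt(cell):
        if isinstance(cell, tuple):
            da, cat = cell
            return f"{round(da, decimals):g} {cat}"
        return cell

    return table.map(fmt)
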