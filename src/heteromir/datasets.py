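"""Published summary tables of the maize jointing-stage heterosis study.

The study crossed four hybrids of the Reid x Tang-SPT heterotic pattern —
Zhengdan 958 (Zheng 58 x Chang 7-2), Anyu 5 (Ye 478 x Chang 7-2),
Ye 478 x Huangzaosi and Zheng 58 x Huangzaosi — and classified the miRNAs
differentially expressed between each hybrid and its parents by the D/A
statistic.  This module ships the printed per-miRNA (D/A, category) cells
and the study's summary counts as machine-readable fixtures, plus a
synthetic reconstruction of the four scaled ID sets consistent with every
printed constraint (the full supplementary ID lists are not redistributed
here).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "HYBRIDS",
    "DE_COUNTS",
    "DIRECTION_COUNTS",
    "VENN_COUNTS",
    "load_printed_patterns",
    "reconstruct_scaled_sets",
]

#: the four hybrid combinations, in the study's reporting order
HYBRIDS = (
    "Zhengdan 958",
    "Anyu 5",
    "Ye 478 x Huangzaosi",
    "Zheng 58 x Huangzaosi",
)

#: per-hybrid DE counts versus each parent and their overlap:
#: (n vs maternal, n vs paternal, n common) -> union = scaled set size
DE_COUNTS: dict[str, tuple[int, int, int]] = {
    "Zhengdan 958": (26, 25, 9),
    "Anyu 5": (33, 21, 4),
    "Ye 478 x Huangzaosi": (21, 29, 11),
    "Zheng 58 x Huangzaosi": (25, 31, 9),
}

#: per-hybrid (induced, repressed) scaled-miRNA counts by D/A sign
DIRECTION_COUNTS: dict[str, tuple[int, int]] = {
    "Zhengdan 958": (17, 25),
    "Anyu 5": (23, 27),
    "Ye 478 x Huangzaosi": (18, 21),
    "Zheng 58 x Huangzaosi": (21, 26),
}

#: four-way Venn summary of the scaled sets: co-detected in all four
#: hybrids, and uniquely present per hybrid
VENN_COUNTS = {
    "common_all_four": 13,
    "unique": {
        "Zhengdan 958": 6,
        "Anyu 5": 10,
        "Ye 478 x Huangzaosi": 4,
        "Zheng 58 x Huangzaosi": 11,
    },
}


def load_printed_patterns() -> pd.DataFrame:
    """Printed per-miRNA (D/A, category) cells.

    Columns: table (common | miR156 | miR395 | miR408_528 | miR399),
    mirna_id, hybrid, da, category.  The "common" table holds the 13 miRNAs
    scaled in all four hybrids (52 cells); the family tables hold every
    populated family-pattern cell.  Categories use ASCII symbols
    ("++", "+", "+-", "-", "--").
    """
    path = resources.files("heteromir.data") / "printed_da_patterns.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"da": float})


# Venn regions needed on top of the printed per-miRNA memberships so the
# reconstruction matches every printed summary count simultaneously
# (set sizes 42/50/39/47, 13 common, uniques 6/10/4/11).  Keys are sorted
# hybrid tuples; values are how many synthetic filler IDs to add.
_FILLER_REGIONS: dict[tuple[str, ...], int] = {
    ("Zhengdan 958",): 2,
    ("Anyu 5",): 9,
    ("Ye 478 x Huangzaosi",): 3,
    ("Zheng 58 x Huangzaosi",): 10,
    ("Anyu 5", "Zhengdan 958", "Zheng 58 x Huangzaosi"): 8,
    ("Anyu 5", "Ye 478 x Huangzaosi", "Zhengdan 958"): 2,
    ("Ye 478 x Huangzaosi", "Zhengdan 958", "Zheng 58 x Huangzaosi"): 2,
    ("Anyu 5", "Ye 478 x Huangzaosi", "Zheng 58 x Huangzaosi"): 3,
    ("Ye 478 x Huangzaosi", "Zhengdan 958"): 2,
    ("Anyu 5", "Zheng 58 x Huangzaosi"): 1,
}


def reconstruct_scaled_sets() -> dict[str, set[str]]:
    """Synthetic reconstruction of the four scaled miRNA ID sets.

    The 41 miRNAs printed in the common and family pattern tables enter
    with their real hybrid memberships; the remaining IDs (not printed in
    the paper's main text) are synthetic placeholders ("synthetic-mir-*")
    distributed so that all printed constraints hold at once: set sizes
    42/50/39/47, exactly 13 IDs common to all four hybrids, and unique
    counts 6/10/4/11.  Suitable for exercising Venn/overlap arithmetic,
    not for identifying real miRNAs.
    """
    patterns = load_printed_patterns()
    sets: dict[str, set[str]] = {h: set() for h in HYBRIDS}
    for _, row in patterns.iterrows():
        sets[row["hybrid"]].add(row["mirna_id"])
    counter = 0
    for region, n_fill in _FILLER_REGIONS.items():
        for _ in range(n_fill):
            counter += 1
            name = f"synthetic-mir-{counter:03d}"
            for hybrid in region:
                sets[hybrid].add(name)
    return sets
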