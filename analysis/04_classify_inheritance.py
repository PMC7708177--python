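#!/usr/bin/env python
"""Classify scaled miRNAs by D/A into the five inheritance modes; tally
induced/repressed, build family tables and the four-way Venn; verify the
classifier against every printed study cell and measure recovery of the
planted classes.

Reads results/simdata/ and results/de/ (run 01 and 03 first); writes
results/classify/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from heteromir import evaluation as ev
from heteromir import io
from heteromir.expression import tpm_normalize
from heteromir.heterosis import (
    classify_triad_table,
    cross_hybrid_overlap,
    tally_direction,
)

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "classify"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts(BASE / "simdata" / "counts.tsv")
    design = io.TriadDesign.read_tsv(BASE / "simdata" / "design.tsv")
    truth = pd.read_csv(BASE / "simdata" / "truth.tsv", sep="\t")
    tpm = tpm_normalize(counts)

    scaled_sets, tallies = {}, []
    for triad in design.triads:
        ids = [
            l.strip()
            for l in (BASE / "de" / f"{triad}_scaled_ids.txt").read_text().splitlines()
            if l.strip()
        ]
        scaled_sets[triad] = set(ids)
        table = classify_triad_table(
            tpm, design.samples(triad, "hybrid"), design.samples(triad, "maternal"),
            design.samples(triad, "paternal"), triad, mirnas=ids,
        )
        table.assign(da=table["da"].round(2)).to_csv(
            OUT / f"{triad}_da.tsv", sep="\t", index=False
        )
        tally = tally_direction([None if np.isnan(v) else v for v in table["da"]])
        tallies.append({"triad": triad, "induced": tally.n_induced,
                        "repressed": tally.n_repressed,
                        "percent_repressed": tally.percent_repressed})
        tt = truth[truth["triad"] == triad].set_index("mirna")
        scaled_truth = tt.loc[[m for m in ids if m in tt.index], "category"]
        est = table.set_index("mirna").loc[scaled_truth.index, "category"]
        print(f"{triad}: {tally.n_induced} induced / {tally.n_repressed} repressed "
              f"({tally.percent_repressed}% repressed); planted class recovered for "
              f"{(est == scaled_truth).mean():.0%} of scaled miRNAs")
    pd.DataFrame(tallies).to_csv(OUT / "direction_tallies.tsv", sep="\t", index=False)

    regions = cross_hybrid_overlap(scaled_sets)
    pd.DataFrame(
        [{"triads": " & ".join(k), "count": v} for k, v in sorted(regions.items())]
    ).to_csv(OUT / "venn_regions.tsv", sep="\t", index=False)
    print("co-detected in all four simulated triads:", regions[tuple(sorted(scaled_sets))])

    # checks against the published tables
    matches, total = ev.printed_pattern_concordance()
    print(f"printed (D/A, category) cells reproduced: {matches}/{total}")
    pct = ev.percent_repressed_from_printed_counts()
    print("published repressed percentages reproduced:", pct)
    common, uniques = ev.venn_from_reconstruction()
    print(f"published Venn reproduced: {common} common, uniques {uniques}")
    pd.DataFrame(
        [{"check": "printed_cells", "matched": matches, "total": total},
         {"check": "venn_common", "matched": common, "total": 13}]
    ).to_csv(OUT / "published_checks.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
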