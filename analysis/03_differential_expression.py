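#!/usr/bin/env python
"""Differential expression per triad: TPM, hybrid-vs-parent t-tests, scaled
unions — plus the union arithmetic check against the published counts.

Reads the cohort from results/simdata/ (run 01 first); writes per-triad DE
tables and a union summary under results/de/.
"""

from pathlib import Path

import pandas as pd

from heteromir import evaluation as ev
from heteromir import io
from heteromir.expression import differential_test, scaled_union, tpm_normalize

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "simdata"
OUT = BASE / "de"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts(SIM / "counts.tsv")
    design = io.TriadDesign.read_tsv(SIM / "design.tsv")
    tpm = tpm_normalize(counts)

    rows, de_frames = [], []
    for triad in design.triads:
        hyb = design.samples(triad, "hybrid")
        sig = {}
        for role in ("maternal", "paternal"):
            de = differential_test(
                tpm, hyb, design.samples(triad, role),
                contrast=f"{triad}:hybrid_vs_{role}",
            )
            de_frames.append(de)
            sig[role] = de.loc[de["significant"], "mirna"]
        union = scaled_union(sig["maternal"], sig["paternal"])
        rows.append(
            {"triad": triad, "vs_maternal": union.n_vs_maternal,
             "vs_paternal": union.n_vs_paternal, "common": union.n_common,
             "union": union.n_union}
        )
        (OUT / f"{triad}_scaled_ids.txt").write_text(
            "\n".join(sorted(union.union)) + "\n"
        )
        print(f"{triad}: {union.n_vs_maternal} vs maternal, {union.n_vs_paternal} "
              f"vs paternal ({union.n_common} common) -> union {union.n_union}")

    de_all = pd.concat(de_frames, ignore_index=True)
    de_all[de_all["significant"]].round({"log2fc": 3, "p_value": 6}).to_csv(
        OUT / "de_significant.tsv", sep="\t", index=False
    )
    pd.DataFrame(rows).to_csv(OUT / "union_summary.tsv", sep="\t", index=False)

    published = ev.union_sizes_from_printed_counts()
    pd.DataFrame(
        [{"hybrid": h, "union": u} for h, u in published.items()]
    ).to_csv(OUT / "published_union_check.tsv", sep="\t", index=False)
    print("published per-side counts reproduce unions:", published)


if __name__ == "__main__":
    main()
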