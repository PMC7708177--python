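#!/usr/bin/env python
"""Simulate the study cohort: four hybrid/parent triads with planted
inheritance modes, plus degradome and qPCR fixtures.

Writes counts/design/truth tables per hybrid under results/simdata/ and
prints the planted class composition.  Downstream drivers (02-06) consume
these files, so run this first.
"""

from pathlib import Path

import pandas as pd

from heteromir import io
from heteromir.datasets import HYBRIDS
from heteromir.synthetic import (
    PlantedSite,
    TriadSimConfig,
    make_transcript_with_site,
    simulate_degradome_library,
    simulate_qpcr_cts,
    simulate_triads,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simdata"
SEED = 2020
MIRNAS = {
    "mirA": "TGACAGAAGAGAGTGAGCAC",
    "mirB": "TTGGACTGAAGGGAGCTCCCT",
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    frames, designs, truths = [], [], []
    for i, hybrid in enumerate(HYBRIDS):
        triad = hybrid.replace(" ", "_")
        config = TriadSimConfig(n_mirnas=150, dispersion=0.05, seed=SEED + i)
        counts, design, truth = simulate_triads(config, triad=triad)
        frames.append(counts)
        designs.append(design.table)
        truths.append(truth.assign(triad=triad))
        print(f"{hybrid}: planted classes", truth["category"].value_counts().to_dict())

    io.write_counts(pd.concat(frames, axis=1), OUT / "counts.tsv")
    io.TriadDesign(pd.concat(designs, ignore_index=True)).write_tsv(OUT / "design.tsv")
    pd.concat(truths, ignore_index=True).round(4).to_csv(OUT / "truth.tsv", sep="\t", index=False)

    # degradome: one planted site per miRNA, background noise elsewhere
    transcripts, planted = {}, []
    for j, (mid, mseq) in enumerate(MIRNAS.items()):
        tid = f"tx{j}"
        transcripts[tid] = make_transcript_with_site(mseq, 450, 220 + 10 * j, seed=SEED + j)
        planted.append(PlantedSite(mseq, tid, 220 + 10 * j, 30))
    reads = simulate_degradome_library(transcripts, planted, background_rate=0.02, seed=SEED)
    io.write_fasta(transcripts, OUT / "transcripts.fa")
    io.write_fasta(reads, OUT / "degradome_reads.fa")
    io.write_fasta(MIRNAS, OUT / "mature_mirnas.fa")
    print(f"degradome: {len(reads)} reads, {len(planted)} planted sites")

    # qPCR: calibrator plus two hybrids with known relative expression
    ct = simulate_qpcr_cts(
        {"parent_cal": 1.0, "hybrid_lo": 0.4, "hybrid_hi": 2.5},
        noise_sd=0.15, n_reps=3, seed=SEED,
    )
    io.write_ct_table(ct, OUT / "ct_table.tsv")
    print(f"qPCR: {ct['sample'].nunique()} samples x 3 replicates -> {OUT}")


if __name__ == "__main__":
    main()
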