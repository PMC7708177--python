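# heteromir

Analysis pipeline for **miRNA inheritance in hybrid/parent triads**, built
around the maize jointing-stage heterosis design: four F1 hybrid
combinations of the Reid × Tang-SPT heterotic pattern (Zhengdan 958,
Anyu 5, Ye 478 × Huangzaosi, Zheng 58 × Huangzaosi) and their parental
inbred lines, sequenced as small-RNA libraries in maternal/paternal/F1
triads with three replicates each.

It is aimed at researchers asking how small-RNA expression is inherited in
F1 hybrids: which miRNAs deviate from their parents, in which direction,
and whether their degradome-supported targets tie the deviation to a
biological process such as photosynthesis.

## The statistic at the core

For each miRNA with replicate-mean TPM abundances P1, P2 (parents) and F1
(hybrid), let MP = (P1 + P2)/2 (mid-parent) and HP = max(P1, P2)
(high-parent). The dominance/additivity ratio

    D/A = (F1 − MP) / (HP − MP)

scales the hybrid's dominance deviation by the additive half-range and
classifies each *scaled* miRNA (one differentially expressed between the
hybrid and at least one parent, P < 0.01 and |log2FC| > 1 by t-test on
TPM) into five inheritance modes:

| mode | meaning                    | interval          |
|------|----------------------------|-------------------|
| `++` | extremely high parental    | D/A > 2           |
| `+`  | high parental              | 0.5 < D/A ≤ 2     |
| `+−` | additive                   | −0.5 ≤ D/A ≤ 0.5  |
| `−`  | low parental               | −2 ≤ D/A < −0.5   |
| `−−` | extremely low parental     | D/A < −2          |

D/A > 0 is *induced*, D/A < 0 *repressed*. Around this sit the supporting
stages: sRNA length/class profiling, exact matching against a mature-miRNA
reference, degradome (PARE) cleavage-site calling with plant-standard
duplex penalties and T-plot categories 0–4, hypergeometric term
enrichment, 2^−ΔΔCt relative expression, and Fisher's-LSD group letters —
plus synthetic-data generators that plant known truth for every stage.

## Worked example

```python
from heteromir.synthetic import TriadSimConfig, simulate_triads
from heteromir.expression import tpm_normalize, differential_test, scaled_union
from heteromir.heterosis import classify_triad_table, tally_direction

counts, design, truth = simulate_triads(TriadSimConfig(n_mirnas=150, seed=2020))
tpm = tpm_normalize(counts)
hyb = design.samples("triad1", "hybrid")
sig = {}
for role in ("maternal", "paternal"):
    de = differential_test(tpm, hyb, design.samples("triad1", role))
    sig[role] = de.loc[de["significant"], "mirna"]
union = scaled_union(sig["maternal"], sig["paternal"])
table = classify_triad_table(tpm, hyb, design.samples("triad1", "maternal"),
                             design.samples("triad1", "paternal"), "triad1",
                             mirnas=sorted(union.union))
tally = tally_direction(list(table["da"]))
print(union.n_vs_maternal, union.n_vs_paternal, union.n_common, union.n_union)
print(tally.n_induced, tally.n_repressed, tally.percent_repressed)
```

prints

```
39 37 16 60
17 43 72
```

i.e. 39 miRNAs are differentially expressed versus the maternal parent and
37 versus the paternal parent (16 in common), giving a scaled union of 60;
of these, 17 are induced and 43 repressed (72 % repressed) by the sign of
their D/A value.

The same flow is available from the shell (`heteromir simulate triads`,
`heteromir de`, `heteromir classify`, `heteromir degradome`,
`heteromir run --config run.yaml`), and the numbered scripts under
`analysis/` run the whole study on synthetic cohorts, writing their tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + degradome + qPCR fixtures
python analysis/02_profile_srna.py         # length/class profile, miRBase matching
python analysis/03_differential_expression.py
python analysis/04_classify_inheritance.py # D/A modes, tallies, Venn, families
python analysis/05_degradome_targets.py
python analysis/06_enrichment_qpcr.py
```

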