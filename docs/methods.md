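# Methods

This note documents the models and procedures implemented in `heteromir`,
the defaults they run with, and what the synthetic-data tests do and do not
establish about real data.

## Expression quantification and differential expression

Counts are normalized per sample to transcripts per million:
`tpm_ij = count_ij × 10^6 / Σ_i count_ij`, with the denominator the total
miRNA-assigned reads of that sample. An all-zero sample is rejected rather
than silently propagated.

A miRNA is differentially expressed between a hybrid and one parent when a
two-sided two-sample t-test on the replicate TPM values gives P < `alpha`
(default 0.01, raw p-values — the convention for this analysis is a raw
cutoff; Benjamini–Hochberg can be layered on by the caller) **and**
|log2FC| > `lfc_threshold` (default 1), where
`log2FC = log2(mean_hybrid + c) − log2(mean_parent + c)` with pseudocount
`c = 1` TPM guarding zeros.

**t-test variant.** The default pools the two group variances (Student,
4 error df at n = 3). The Welch correction is available
(`ttest="welch"`) but is not the default: with three replicates Welch's
df collapses toward 2, whose P < 0.01 critical value (≈ 9.9) exceeds the
largest t-statistic three replicates can produce once the replicate CV is
in the 20 % range (|t| ≤ √3/CV ≈ 7.7) — an estimator that cannot reject is
not a faithful reconstruction of an analysis that reported 21–33
detections per contrast at n = 3. Rows with zero variance in both groups
get P = 1 when the means agree and P = 0 otherwise.

The *scaled* set of a hybrid is the union of its two parental DE sets;
|A ∪ B| = |A| + |B| − |A ∩ B| is reported alongside the per-side counts.

## D/A classification

For replicate-mean TPMs (F1, P1, P2): MP = (P1+P2)/2, HP = max(P1, P2),
`D/A = (F1 − MP)/(HP − MP)`. Five modes: `++` (D/A > 2), `+`
(0.5 < D/A ≤ 2), `+−` (−0.5 ≤ D/A ≤ 0.5), `−` (−2 ≤ D/A < −0.5), `−−`
(D/A < −2). The published intervals are open at all four thresholds and
leave boundary values unassigned; here boundaries go to the **less
extreme** class, a choice consistent with every published table cell (none
sits on a boundary). D/A is computed from replicate means, not averaged
per-replicate ratios. When `HP − MP < 1e-9 × max(1, HP)` the parents are
numerically indistinguishable and D/A is undefined (excluded from
induced/repressed tallies together with exact zeros, both reported
separately). `percent_repressed` uses round-half-up, which reproduces the
published 25/42 → 60 %, 21/39 → 54 %, 26/47 → 55 %.

## sRNA profiling

Reads outside 18–30 nt fall into an explicit "other" length bucket.
Class annotation assigns each placed read exactly one label; when a read
overlaps several feature types the fixed precedence
miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon > intron makes the
assignment deterministic (structural small-RNA annotation wins over genic
context); exon/intron hits split into sense/antisense by strand agreement.
Mature-miRNA matching is exact full-length string equality after U→T
normalization, over reads of 18–25 nt; multi-matching reads count toward
every matching entry and flag them `multi_hit`. No read aligner is
embedded: placements come with the reads (the generator provides them),
and intervals are handled internally as 0-based half-open (GFF3 read as
1-based inclusive, BED as 0-based half-open).

## Degradome cleavage-site calling

Read prefixes (default 20 nt, minimum 15) are matched as exact substrings
of the sense transcript; every occurrence increments the profile at the
position of the read's 5′-most base. Duplex scoring is the standard plant
penalty scheme on ungapped antiparallel alignments: Watson–Crick 0, G:U
wobble 0.5, mismatch 1, doubled at miRNA positions 2–13; candidate windows
with score ≤ `max_score` (default 7) nominate the transcript base paired
to miRNA position 10 as the cleavage position — canonical AGO slicing
geometry, between the bases paired to miRNA 10–11. Site categories follow
T-plot practice: 0 unique transcript maximum, 1 tied maximum, 2 above the
median of non-zero positions, 3 at/below that median, 4 a single read. A
single-read site is category 4 even when it happens to be the maximum.
Bulged (gapped) duplexes are not called — a deliberate simplification;
genuinely bulged targets will be missed.

## Enrichment, 2^−ΔΔCt and LSD letters

Term enrichment is an upper-tail hypergeometric test
P(X ≥ k | N, K, n) per term of a user-supplied gene→term table (no live
ontology, no hierarchy propagation), significant at raw P < 0.05; terms
with k = 0 are omitted as uninformative. Relative expression follows the
Livak convention: ΔCt = target − reference per replicate, averaged per
sample, then ΔΔCt against the calibrator and fold = 2^−ΔΔCt (amplification
efficiency fixed at 2). Group letters are Fisher's LSD after one-way
ANOVA: pair (i, j) differs when
|mean_i − mean_j| > t(1−α/2, df_e)·√(MSE(1/n_i + 1/n_j)); one letter per
maximal clique of the non-significance graph, ordered from the highest
mean, so two groups share a letter iff they are not significantly
different.

## Synthetic-data generators

`simulate_triads` emulates one maternal/paternal/F1 triad with three
replicate libraries per genotype. Per miRNA: a base abundance is drawn
log-uniformly from `parent_mean_range` (default 20–2000 TPM, mimicking the
right-skewed abundance spectrum of real miRNA libraries); one parent
(random side) is `parent_divergence` times the other (default 2); an
inheritance mode is drawn from `class_mix` (default 15/15/25/30/15 % for
`++/+/+−/−/−−`, repressed-leaning as in the hybrids this design emulates);
the planted D/A is uniform within the mode's interval, truncated at ±6 and
at the bound keeping F1 ≥ 0 (−(1+d)/(d−1), i.e. −3 at divergence 2); the
F1 mean is then exactly MP + D/A·(HP − MP). Counts are negative binomial
with variance m + αm² (dispersion α defaults to 0.05; α = 0 yields the
exact expected values as floats, so the noise-free limit round-trips
through TPM and D/A to < 1e-9 — integer rounding would break that exact
identity, which is why dispersion-0 output is not rounded). Expected
totals are `library_size` (default 2×10⁶). Because TPM renormalizes every
sample to its own total, the planted D/A only survives normalization if
all genotypes share one planted total: a balancing remainder row
(`mirOTHER`, the rest of the small-RNA pool) closes the composition and is
excluded from the truth table. With `parent_divergence = 1` the parents
coincide, every D/A is undefined and the simulation is a pure null for
type-I checks.

`simulate_srna_reads` lays one feature block per annotation class on a
synthetic chromosome (unannotated gaps between), then places reads by a
chosen class and length profile — antisense classes on the minus strand —
with random sequences. `simulate_degradome_library` emits `peak_reads`
reads whose 5′ end is the planted cleavage position (validating the
planted duplex against `max_score`) plus per-position Poisson background
on the sense strand only, matching what degradome sequencing captures.
`simulate_qpcr_cts` inverts the ΔΔCt model — target Ct =
reference + ΔCt_calibrator − log2(fold) — with Gaussian noise on the
target Ct only, so the log2 fold-change error propagates as
`noise_sd·√(2/n)`.

What the generators do **not** emulate: sequencing error, adapters,
quality strings, mapping ambiguity from a real genome, miRNA families
sharing near-identical sequences, and between-genotype correlation
structure. Passing tests therefore establish the estimators' correctness
and calibration on the stated noise model, not performance on any real
library.

## Problem sizes and measured operating characteristics

The recovery and power measurements (`heteromir.evaluation`) run at 1000
simulated miRNAs, 3 replicates, dispersion 0.05, and 20 degradome
libraries of 3 planted sites each — sizes at which each measurement
completes in seconds while leaving Monte-Carlo error well below the
effects measured.

Two characteristics of the study-condition defaults are worth stating
plainly, because they are properties of the design, not implementation
defects. At dispersion 0.05 the per-replicate CV is
√(1/count + 0.05) ≥ 22 %, so the mean-of-three D/A estimate carries a
standard error of roughly 0.3–0.5 D/A units at parent divergence 2;
against class boundaries only 0.25 away, classification recovery for
boundary-adjacent miRNAs plateaus near 80 % (100 % and < 1e-9 D/A error at
dispersion 0). Likewise the t-test's power at exactly 4× planted fold and
P < 0.01 with n = 3 reaches ≈ 0.87 (Student) — the 22 % CV floor caps the
attainable t-statistic — while the null pass rate stays calibrated at
≈ 0.01. Recovering ≥ 95 % of boundary-adjacent classes or ≥ 0.9 power at
4× would require dispersion ≤ ~0.01 (per-replicate CV ≤ 10 %) or more
replicates; the defaults are kept at the stated study conditions rather
than tuned to flatter numbers.

## Known limitations

- Ungapped duplexes only; no p-value machinery for degradome sites.
- Exact-match read counting: no mismatch tolerance against the mature
  reference, no multi-mapping resolution beyond per-hit counting.
- The published scaled ID sets are only partially printed; the four-way
  overlap check runs on a synthetic reconstruction
  (`datasets.reconstruct_scaled_sets`) that honours every printed
  constraint but does not name the unprinted miRNAs.
- The enrichment background and the GO hierarchy are the caller's
  responsibility; the test is a flat hypergeometric.
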