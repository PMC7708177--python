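"""TPM normalization and hybrid-vs-parent differential expression.

The differential test follows the small-RNA convention of the study design
this package emulates: per-miRNA two-sample t-test on replicate TPM values,
with a miRNA called differentially expressed when P < alpha (default 0.01,
no multiple-testing correction) AND |log2 fold change| > a threshold
(default 1).  The fold change is a ratio of replicate-mean TPMs with a
pseudocount guarding against zeros.

The default t-test pools the two group variances (Student).  With three
replicates per group, the Welch correction collapses to ~2 degrees of
freedom, which places the P < 0.01 critical value above the largest
t-statistic three replicates can produce at realistic count dispersion —
pooled variance is the variant consistent with small-n sRNA practice.
Welch remains available via ``ttest="welch"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["tpm_normalize", "differential_test", "scaled_union", "UnionSummary"]


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to transcripts per million.

    value_ij = count_ij * 1e6 / column_total_j.  Raises when a column sums
    to zero (the sample would be undefined), naming the sample.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cannot TPM-normalize all-zero sample column(s): {list(zero.index)}"
        )
    return counts * 1e6 / totals


def differential_test(
    tpm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "a_vs_b",
    pseudocount: float = 1.0,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    ttest: str = "student",
) -> pd.DataFrame:
    """Per-miRNA t-test and log2 fold change between two replicate groups.

    log2FC = log2(mean_a + pseudocount) - log2(mean_b + pseudocount); for a
    hybrid-vs-parent contrast pass the hybrid replicates as ``group_a``.
    Rows with zero variance in both groups get P = 1 when the means are
    equal (no evidence of difference by convention) and P = 0 otherwise.

    Returns a DataFrame with columns mirna, contrast, log2fc, p_value,
    significant (significant <=> p_value < alpha and |log2fc| > threshold).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates for a t-test")
    if ttest not in ("student", "welch"):
        raise ValueError(f"ttest must be 'student' or 'welch', got {ttest!r}")
    a = tpm[list(group_a)].to_numpy(dtype=float)
    b = tpm[list(group_b)].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=(ttest == "student"))
    # degenerate rows: no variance anywhere
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(var0, np.where(mean_a == mean_b, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    out = pd.DataFrame(
        {
            "mirna": tpm.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p_value": p,
            "significant": (p < alpha) & (np.abs(log2fc) > lfc_threshold),
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class UnionSummary:
    """Union of the two hybrid-vs-parent DE sets of one hybrid."""

    union: frozenset[str]
    n_vs_maternal: int
    n_vs_paternal: int
    n_common: int

    @property
    def n_union(self) -> int:
        return len(self.union)


def scaled_union(
    de_vs_maternal: Iterable[str], de_vs_paternal: Iterable[str]
) -> UnionSummary:
    """Union of significant miRNA IDs from the two parental contrasts.

    |union| = |A| + |B| - |A and B|; the union is the "scaled" candidate set
    passed on to D/A classification.
    """
    a = set(de_vs_maternal)
    b = set(de_vs_paternal)
    return UnionSummary(
        union=frozenset(a | b),
        n_vs_maternal=len(a),
        n_vs_paternal=len(b),
        n_common=len(a & b),
    )
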