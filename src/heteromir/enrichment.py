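"""Term enrichment for target-gene sets and qPCR verification statistics.

Enrichment is an upper-tail hypergeometric test per annotation term against
a user-supplied gene -> term map (no live ontology); relative expression is
the Livak 2^-ddCt method against a reference gene and a calibrator sample;
group letters come from Fisher's LSD after one-way ANOVA.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hypergeometric_enrichment",
    "delta_delta_ct",
    "lsd_groups",
]


def hypergeometric_enrichment(
    target_genes: Iterable[str],
    background: Iterable[str],
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    For a term annotating K of the N background genes, of which k fall in
    the n-gene target set, p = P(X >= k) with X ~ Hypergeom(N, K, n).
    ``annotation`` is either a DataFrame with columns gene, term[, label]
    or a mapping gene -> iterable of terms.  Terms absent from the target
    set (k = 0) are omitted.  Results are sorted by p-value; a term is
    significant when p < ``alpha`` (no correction, matching the raw-cutoff
    convention).
    """
    targets = set(target_genes)
    bg = set(background)
    offenders = sorted(targets - bg)
    if offenders:
        raise ValueError(f"target genes not in background: {offenders}")

    if isinstance(annotation, pd.DataFrame):
        ann = annotation
    else:
        ann = pd.DataFrame(
            [(g, t) for g, terms in annotation.items() for t in terms],
            columns=["gene", "term"],
        )
    if "label" not in ann.columns:
        ann = ann.assign(label=ann["term"])
    ann = ann[ann["gene"].isin(bg)].drop_duplicates(["gene", "term"])

    N, n = len(bg), len(targets)
    rows = []
    for term, sub in ann.groupby("term"):
        K = sub["gene"].nunique()
        k = sub["gene"].isin(targets).sum()
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "label": sub["label"].iloc[0],
                "k": int(k),
                "K": int(K),
                "n": n,
                "N": N,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "label", "k", "K", "n", "N", "p_value", "significant"]
    )
    return out.sort_values(["p_value", "term"], ignore_index=True)


def delta_delta_ct(ct_table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` rows: sample, replicate, target_ct, reference_ct.  Per
    replicate dCt = target_ct - reference_ct; dCt is averaged per sample
    first, then ddCt = mean dCt(sample) - mean dCt(calibrator) and
    fold = 2^-ddCt (the Livak convention: average, then difference).

    Returns a DataFrame with columns sample, delta_ct, delta_delta_ct,
    fold_change; the calibrator row has ddCt 0 and fold 1 exactly.
    """
    required = {"sample", "target_ct", "reference_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct_table[ct_table["reference_ct"].isna() | ct_table["target_ct"].isna()]
    if len(bad):
        raise ValueError(f"missing Ct values in rows: {list(bad.index)}")
    if calibrator not in set(ct_table["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not in Ct table")

    dct = (
        ct_table.assign(delta_ct=ct_table["target_ct"] - ct_table["reference_ct"])
        .groupby("sample", sort=False)["delta_ct"]
        .mean()
    )
    ddct = dct - dct[calibrator]
    return pd.DataFrame(
        {
            "sample": dct.index,
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold_change": np.power(2.0, -ddct.to_numpy()),
        }
    ).reset_index(drop=True)


def _maximal_cliques(adjacency: dict[str, set[str]]) -> list[frozenset[str]]:
    """All maximal cliques of a small graph by subset enumeration."""
    nodes = sorted(adjacency)
    if len(nodes) > 16:
        raise ValueError("letter assignment supports at most 16 groups")
    cliques: list[frozenset[str]] = []
    for r in range(len(nodes), 0, -1):
        for combo in itertools.combinations(nodes, r):
            s = frozenset(combo)
            if any(s <= c for c in cliques):
                continue
            if all(b in adjacency[a] for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    return cliques


def lsd_groups(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Fisher's LSD compact letter display after one-way ANOVA.

    Two groups differ significantly when |mean_i - mean_j| exceeds
    LSD_ij = t(1 - alpha/2, df_error) * sqrt(MSE * (1/n_i + 1/n_j)), with
    MSE and df_error from the one-way ANOVA residual.  Letters are assigned
    one per maximal clique of the non-significance graph, ordered from the
    clique containing the highest mean; two groups share a letter iff they
    are not significantly different.
    """
    if len(values) < 2:
        raise ValueError("lsd_groups needs at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} needs at least two replicates")
    N = sum(len(a) for a in arrays.values())
    k = len(arrays)
    df_error = N - k
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_error
    tcrit = stats.t.ppf(1 - alpha / 2, df_error)
    means = {g: a.mean() for g, a in arrays.items()}

    groups = sorted(arrays)
    adjacency: dict[str, set[str]] = {g: set() for g in groups}
    for g1, g2 in itertools.combinations(groups, 2):
        lsd = tcrit * math.sqrt(mse * (1 / len(arrays[g1]) + 1 / len(arrays[g2])))
        if abs(means[g1] - means[g2]) <= lsd:
            adjacency[g1].add(g2)
            adjacency[g2].add(g1)

    cliques = _maximal_cliques(adjacency)
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letter_of_clique = {}
    for i, clique in enumerate(cliques):
        letter_of_clique[clique] = chr(ord("a") + i)
    letters = {
        g: "".join(sorted(letter_of_clique[c] for c in cliques if g in c)) for g in groups
    }
    return letters
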