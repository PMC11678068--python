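"""Group-level selection summaries: incidence of positive selection,
per-group rate profiles with significance letters, and per-chromosome
summaries.

"Incidence" is the fraction of loci with ω > 1 in a group; association
between grouping and positive-selection status is tested with a Pearson
chi-square on the G×2 contingency table (no continuity correction).
Group profiles report per-group mean/sd plus a one-way ANOVA and pairwise
Welch t-tests summarised as a compact letter display: groups sharing a
letter are not significantly different at the chosen α.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "incidence_by_group",
    "group_profile",
    "chromosome_summary",
    "compact_letter_display",
]


def incidence_by_group(loci: pd.DataFrame, grouping: pd.Series) -> dict:
    """ω>1 incidence per group with a chi-square test of association.

    ``grouping`` is a per-locus label Series aligned with ``loci``.
    Returns a dict with a per-group table (n, n_positive, fraction) and
    the chi-square statistic/df/p of the group × positive-status table.
    Empty groups are dropped with a warning.
    """
    df = pd.DataFrame(
        {"group": grouping.reindex(loci.index), "positive": loci["omega"] > 1}
    ).dropna(subset=["group"])
    counts = df.groupby("group", sort=False).agg(
        n_loci=("positive", "size"), n_positive=("positive", "sum")
    )
    empty = counts[counts["n_loci"] == 0]
    if len(empty):
        warnings.warn(f"dropping empty groups {list(empty.index)}", stacklevel=2)
        counts = counts[counts["n_loci"] > 0]
    if len(counts) < 2:
        raise ValueError("need at least 2 nonempty groups")
    counts["fraction"] = counts["n_positive"] / counts["n_loci"]
    table = np.column_stack(
        [counts["n_positive"], counts["n_loci"] - counts["n_positive"]]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, df_, p = 0.0, 0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=False)
        chi2, df_, p = float(res.statistic), int(res.dof), float(res.pvalue)
    return {"table": counts.reset_index(), "chi2": chi2, "df": df_, "p": p}


def compact_letter_display(
    labels: list, p_matrix: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Assign significance letters from a pairwise p-value matrix.

    The insert-and-absorb convention: start with one letter covering all
    groups; every significant pair splits the letters containing both;
    letters contained in another are absorbed.  Groups share a letter iff
    they are not significantly different at ``alpha``.
    """
    letter_groups: list[set] = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if p_matrix.loc[a, b] > alpha:
                continue
            next_groups: list[set] = []
            for grp in letter_groups:
                if a in grp and b in grp:
                    next_groups.append(grp - {a})
                    next_groups.append(grp - {b})
                else:
                    next_groups.append(grp)
            # absorb duplicates and subsets
            letter_groups = [
                g for k, g in enumerate(next_groups)
                if g and not any(
                    (g < h) or (g == h and k > j) for j, h in enumerate(next_groups)
                )
            ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, grp in zip(alphabet, letter_groups):
        for lab in labels:
            if lab in grp:
                out[lab] += letter
    return out


def group_profile(
    loci: pd.DataFrame,
    grouping: pd.Series,
    value: str = "omega",
    alpha: float = 0.05,
    bh_correct: bool = False,
    order: list | None = None,
) -> dict:
    """Per-group mean/sd/n of a rate column with ANOVA and Welch letters.

    ``value`` is one of the locus-table rate columns (ω, Ks or the
    phylostratum).  Degenerate groups (fewer than two finite values) are
    skipped with a warning.  ``bh_correct`` applies Benjamini–Hochberg to
    the pairwise p-values before letter assignment.
    """
    vals = pd.DataFrame(
        {"group": grouping.reindex(loci.index), "value": pd.to_numeric(loci[value], errors="coerce")}
    ).dropna()
    groups: dict = {}
    for lab, sub in vals.groupby("group", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if len(v) < 2:
            warnings.warn(f"group {lab!r} has fewer than 2 values; skipped", stacklevel=2)
            continue
        groups[lab] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 values")
    labels = order if order is not None else list(groups)
    labels = [lab for lab in labels if lab in groups]
    anova_p = float(stats.f_oneway(*[groups[lab] for lab in labels]).pvalue)
    p_mat = pd.DataFrame(1.0, index=labels, columns=labels)
    pairs = list(combinations(labels, 2))
    raw_p = []
    for a, b in pairs:
        p = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        raw_p.append(p)
    if bh_correct and raw_p:
        order_idx = np.argsort(raw_p)
        m = len(raw_p)
        adj = np.empty(m)
        prev = 1.0
        for rank, i in enumerate(reversed(order_idx), start=0):
            k = m - rank
            prev = min(prev, raw_p[i] * m / k)
            adj[i] = prev
        raw_p = list(adj)
    for (a, b), p in zip(pairs, raw_p):
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    letters = compact_letter_display(labels, p_mat, alpha=alpha)
    table = pd.DataFrame(
        {
            "group": labels,
            "n": [len(groups[lab]) for lab in labels],
            "mean": [float(np.mean(groups[lab])) for lab in labels],
            "sd": [float(np.std(groups[lab], ddof=1)) for lab in labels],
            "letters": [letters[lab] for lab in labels],
        }
    )
    return {"table": table, "anova_p": anova_p, "pairwise_p": p_mat}


def chromosome_summary(loci: pd.DataFrame, n_genome: int | None = None) -> dict:
    """Per-chromosome locus counts, mean Ks/ω, and pairwise ω Welch tests.

    ``n_genome`` (total loci per chromosome before filtering, as a mapping
    or None) controls the "fraction analysed" column.  With a single
    chromosome the test matrix is skipped.
    """
    if "chromosome" not in loci.columns:
        raise ValueError("locus table lacks a chromosome column")
    rows = []
    groups: dict = {}
    for chrom, sub in loci.groupby("chromosome", sort=False):
        omega = sub["omega"].dropna().to_numpy(dtype=float)
        groups[chrom] = omega
        frac = np.nan
        if n_genome:
            total = n_genome.get(chrom) if hasattr(n_genome, "get") else None
            frac = len(sub) / total if total else np.nan
        rows.append(
            {
                "chromosome": chrom,
                "n": len(sub),
                "fraction_analyzed": frac,
                "mean_ks": float(sub["ks"].mean()),
                "mean_omega": float(sub["omega"].mean()),
            }
        )
    table = pd.DataFrame(rows)
    chroms = list(groups)
    if len(chroms) < 2:
        return {"table": table, "pairwise_p": None}
    p_mat = pd.DataFrame(np.nan, index=chroms, columns=chroms)
    for a, b in combinations(chroms, 2):
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            p = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    np.fill_diagonal(p_mat.values, 1.0)
    return {"table": table, "pairwise_p": p_mat}
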