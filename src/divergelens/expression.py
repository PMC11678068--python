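"""Gene-expression abundance (GEA) and breadth (GEB) metrics.

GEA analyses group loci by expression level into non-overlapping windows
of a fixed number of loci (default 100) and report per-window means, so
each plotted point averages out locus-level noise.  GEB counts the
samples in which a locus is called present (out of 11 by default) and is
classified into not-expressed / specifically expressed (one sample) /
broadly expressed (two or more samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "BreadthClass",
    "present_calls",
    "gea_windows",
    "geb_counts",
    "classify_breadth",
    "gea_tertiles",
]


class BreadthClass(str, Enum):
    """Expression-breadth category of a locus."""

    not_expressed = "not_expressed"  # GEB = 0
    specific = "specific"            # GEB = 1
    broad = "broad"                  # GEB >= 2


def present_calls(records: pd.DataFrame, rpm_threshold: float = 1.0) -> pd.DataFrame:
    """Fill present/absent calls from abundance, per assay.

    EST and cDNA loci are present when at least one sequence was observed
    (abundance >= 1); RNA-Seq loci when abundance >= ``rpm_threshold``
    (inclusive; 1 RPM by default).  Microarray calls come from external
    preprocessing and are left untouched — records without one stay
    missing and are excluded from breadth counting.
    """
    out = records.copy()
    present = out["present"].astype("boolean")
    for assay, thr in (("est", 1.0), ("cdna", 1.0), ("rnaseq_rpm", rpm_threshold)):
        mask = out["assay"] == assay
        present[mask] = out.loc[mask, "abundance"] >= thr
    out["present"] = present
    return out


def gea_windows(
    table: pd.DataFrame,
    assay: str,
    window: int = 100,
) -> pd.DataFrame:
    """Average rate estimates over abundance-sorted windows of loci.

    Loci with zero abundance for the assay are excluded; the remainder are
    sorted by abundance ascending (ties broken by ``locus_id``), cut into
    consecutive disjoint windows of exactly ``window`` loci (any trailing
    partial window is dropped), and per-window means of log10 abundance,
    Ks, ω and phylostratum are reported.
    """
    col = f"gea_{assay}"
    if col not in table.columns:
        raise ValueError(f"analysis table lacks column {col!r}")
    pos = table[table[col] > 0].sort_values([col, "locus_id"], kind="stable")
    n_windows = len(pos) // window
    if n_windows == 0:
        raise ValueError(
            f"need at least {window} loci with positive {assay} abundance, "
            f"got {len(pos)}"
        )
    pos = pos.iloc[: n_windows * window].copy()
    pos["window_rank"] = np.repeat(np.arange(n_windows), window)
    grp = pos.groupby("window_rank")
    out = pd.DataFrame(
        {
            "window_rank": np.arange(n_windows),
            "mean_log10_gea": grp[col].apply(lambda s: float(np.log10(s).mean())),
            "mean_ks": grp["ks"].mean(),
            "mean_omega": grp["omega"].mean(),
            "mean_ps": grp["ps"].mean().astype(float),
            "n_loci": window,
        }
    )
    return out.reset_index(drop=True)


def geb_counts(
    records: pd.DataFrame,
    assay: str,
    n_samples: int = 11,
) -> pd.Series:
    """Per-locus expression breadth: number of samples called present.

    Requires present calls to be filled for the chosen assay (microarray
    records without a call simply do not contribute).  Errors if the data
    contain more distinct samples than ``n_samples``.
    """
    sub = records[records["assay"] == assay]
    n_obs = sub["sample_id"].nunique()
    if n_obs > n_samples:
        raise ValueError(f"data have {n_obs} samples but n_samples={n_samples}")
    geb = sub.groupby("locus_id")["present"].apply(
        lambda s: int((s == True).sum())  # noqa: E712 -- nullable boolean
    )
    geb.name = "geb"
    return geb


def classify_breadth(geb: int | pd.Series) -> BreadthClass | pd.Series:
    """Map a breadth count to its category (0 / 1 / >=2 samples)."""
    if isinstance(geb, pd.Series):
        return geb.map(lambda g: classify_breadth(int(g)).value)
    if geb < 0:
        raise ValueError("breadth cannot be negative")
    if geb == 0:
        return BreadthClass.not_expressed
    if geb == 1:
        return BreadthClass.specific
    return BreadthClass.broad


def gea_tertiles(table: pd.DataFrame, assay: str) -> pd.Series:
    """Rank-based low/medium/high abundance labels, one per locus.

    Group sizes are equal up to one, with the remainder going to the
    lower groups first; ties (including zero abundance, which lands in
    "low") are broken by ``locus_id`` order.
    """
    col = f"gea_{assay}"
    if col not in table.columns:
        raise ValueError(f"analysis table lacks column {col!r}")
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 loci to form tertiles")
    order = table.sort_values([col, "locus_id"], kind="stable").index
    base, rem = divmod(n, 3)
    sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    labels = np.repeat(["low", "medium", "high"], sizes)
    out = pd.Series(index=table.index, dtype=object, name="gea_tertile")
    out.loc[order] = labels
    return out
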