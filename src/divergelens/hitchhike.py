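"""Proximity analysis around putatively positively selected loci.

Loci with ω > 1 (strict) are flagged as anchors.  Every other locus is
assigned its minimum ordinal distance (in loci, along the chromosome;
distances never cross chromosome boundaries) to an anchor, and distance
bands such as 1–5 / 6–10 / 11–15 are compared against the background of
all non-anchor loci with Welch two-sample t-tests on ω.  Elevated ω in
the nearest band is the hitchhiking signature: linkage drags neutral or
weakly constrained neighbours along with a selected locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "INTRASPECIES_BANDS",
    "parse_bands",
    "flag_positive",
    "assign_bands",
    "compare_bands",
]


@dataclass(frozen=True)
class Band:
    """Inclusive ordinal-distance range, e.g. Band("1-5", 1, 5)."""

    label: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"invalid band {self.label}: need 1 <= lo <= hi")


DEFAULT_BANDS = (Band("1-5", 1, 5), Band("6-10", 6, 10), Band("11-15", 11, 15))
INTRASPECIES_BANDS = (Band("1-2", 1, 2), Band("3-4", 3, 4), Band("5-6", 5, 6))


def parse_bands(spec: str) -> tuple[Band, ...]:
    """Parse a band list like ``"1-5,6-10,11-15"``."""
    bands = []
    for part in spec.split(","):
        lo, hi = part.strip().split("-")
        bands.append(Band(part.strip(), int(lo), int(hi)))
    return tuple(bands)


def flag_positive(loci: pd.DataFrame) -> pd.Index:
    """Loci under putative positive selection: ω strictly greater than 1."""
    return pd.Index(loci.loc[loci["omega"] > 1, "locus_id"])


def _check_bands(bands: Sequence[Band]) -> list[Band]:
    bands = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(bands, bands[1:]):
        if b.lo <= a.hi:
            raise ValueError(f"bands {a.label} and {b.label} overlap")
    return bands


def assign_bands(
    loci: pd.DataFrame,
    anchors: pd.Index | Sequence[str],
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Assign each locus its minimum anchor distance and distance band.

    Distances are ordinal (loci away along the chromosome) and computed to
    the nearest anchor on the same chromosome; chromosomes without an
    anchor give distance ∞.  Anchors themselves get distance 0 and band
    "anchor"; every other locus falls in the unique band containing its
    minimum distance, or "background" if none does, so each locus is
    counted exactly once.
    """
    bands = _check_bands(bands)
    anchors = pd.Index(anchors)
    if len(anchors) == 0:
        raise ValueError("no anchor loci (none with ω > 1)")
    unknown = anchors.difference(loci["locus_id"])
    if len(unknown):
        raise ValueError(f"anchors not in locus table: {list(unknown[:3])}")
    out_frames = []
    is_anchor = loci["locus_id"].isin(anchors)
    for _, chrom_df in loci.groupby("chromosome", sort=False):
        chrom_df = chrom_df.sort_values("order_index", kind="stable")
        pos = chrom_df["order_index"].to_numpy(dtype=float)
        anchor_pos = chrom_df.loc[is_anchor.reindex(chrom_df.index), "order_index"]
        anchor_pos = anchor_pos.to_numpy(dtype=float)
        if len(anchor_pos):
            dist = np.abs(pos[:, None] - anchor_pos[None, :]).min(axis=1)
        else:
            dist = np.full(len(pos), np.inf)
        frame = pd.DataFrame(
            {"locus_id": chrom_df["locus_id"].to_numpy(), "min_distance": dist}
        )
        out_frames.append(frame)
    out = pd.concat(out_frames, ignore_index=True)

    def label(d: float) -> str:
        if d == 0:
            return "anchor"
        for b in bands:
            if b.lo <= d <= b.hi:
                return b.label
        return "background"

    out["band"] = out["min_distance"].map(label)
    out["min_distance"] = out["min_distance"].replace(np.inf, np.nan)
    return out


def compare_bands(
    assignments: pd.DataFrame,
    loci: pd.DataFrame,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-band ω summaries with Welch t-tests against background and neighbours.

    The background ("all loci") group is every non-anchor locus, banded or
    not.  For each band the comparison against background and against the
    next band outward is reported (mean, sd, n, t, p); comparisons with a
    group of fewer than two loci are skipped with a warning.
    """
    bands = _check_bands(bands)
    merged = assignments.merge(loci[["locus_id", "omega"]], on="locus_id")
    merged = merged[merged["omega"].notna()]
    non_anchor = merged[merged["band"] != "anchor"]
    groups: dict[str, np.ndarray] = {
        "all_loci": non_anchor["omega"].to_numpy(dtype=float)
    }
    for b in bands:
        groups[b.label] = merged.loc[merged["band"] == b.label, "omega"].to_numpy(dtype=float)

    def welch(a: np.ndarray, b: np.ndarray):
        if len(a) < 2 or len(b) < 2:
            return np.nan, np.nan
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)

    rows = []
    labels = [b.label for b in bands]
    for i, lab in enumerate(labels):
        vals = groups[lab]
        if len(vals) < 2:
            warnings.warn(f"band {lab} has fewer than 2 loci; comparisons skipped",
                          stacklevel=2)
        t_bg, p_bg = welch(vals, groups["all_loci"])
        neighbour = labels[i + 1] if i + 1 < len(labels) else None
        t_nb, p_nb = welch(vals, groups[neighbour]) if neighbour else (np.nan, np.nan)
        rows.append(
            {
                "band": lab,
                "n": len(vals),
                "mean_omega": float(np.mean(vals)) if len(vals) else np.nan,
                "sd_omega": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "t_vs_background": t_bg,
                "p_vs_background": p_bg,
                "adjacent_band": neighbour,
                "t_vs_adjacent": t_nb,
                "p_vs_adjacent": p_nb,
            }
        )
    bg = groups["all_loci"]
    rows.append(
        {
            "band": "all_loci",
            "n": len(bg),
            "mean_omega": float(np.mean(bg)) if len(bg) else np.nan,
            "sd_omega": float(np.std(bg, ddof=1)) if len(bg) > 1 else np.nan,
            "t_vs_background": np.nan,
            "p_vs_background": np.nan,
            "adjacent_band": None,
            "t_vs_adjacent": np.nan,
            "p_vs_adjacent": np.nan,
        }
    )
    return pd.DataFrame(rows)
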