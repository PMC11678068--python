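"""Per-locus tables, expression records and the joined analysis table.

The canonical in-memory containers are pandas DataFrames:

* a *locus table* has one row per gene locus with its evolutionary-rate
  estimates (``ka``, ``ks``, ``omega``), phylostratum (``ps``, an integer
  gene-age class from 1 = most ancient to 13 = youngest), a ``chromosome``
  label and an ``order_index`` giving the ordinal position of the locus
  along its chromosome (all proximity logic downstream works in units of
  "loci away", never base pairs);
* an *expression table* is long-format with one row per
  (locus, sample, assay) carrying a nonnegative ``abundance`` in assay
  units (EST/cDNA counts, RNA-Seq RPM, microarray signal) and a nullable
  boolean ``present`` call;
* the *analysis table* joins the two: one row per locus with per-assay
  total abundance (``gea_<assay>``) and per-assay expression breadth
  (``geb_<assay>`` = number of samples called present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCUS_COLUMNS",
    "ASSAYS",
    "COMPARISONS",
    "LocusRecord",
    "ExpressionRecord",
    "read_locus_table",
    "write_locus_table",
    "read_expression_table",
    "write_expression_table",
    "join_analysis_table",
]

logger = logging.getLogger(__name__)

#: Required columns of a locus table, in canonical order.
LOCUS_COLUMNS = [
    "locus_id",
    "chromosome",
    "order_index",
    "ka",
    "ks",
    "omega",
    "ps",
    "comparison",
]

#: Recognised expression assay tags.
ASSAYS = ("est", "cdna", "rnaseq_rpm", "microarray")

#: Recognised ortholog-comparison depths.
COMPARISONS = ("intergenus", "interspecies", "intraspecies")

#: Markers normalised to a single missing state on read.
NA_MARKERS = ("n.a.", "NA", "")


@dataclass(frozen=True)
class LocusRecord:
    """One gene locus with rate estimates and gene-age annotation."""

    locus_id: str
    chromosome: str = "1"
    order_index: int = 0
    ka: float = np.nan
    ks: float = np.nan
    omega: float = np.nan
    ps: int | None = None
    comparison: str = "interspecies"

    def __post_init__(self) -> None:
        if self.ps is not None and not (1 <= self.ps <= 13):
            raise ValueError(f"ps must be in [1, 13], got {self.ps}")
        if self.comparison not in COMPARISONS:
            raise ValueError(f"unknown comparison {self.comparison!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """One (locus, sample) abundance measurement for a given assay."""

    locus_id: str
    sample_id: str
    assay: str
    abundance: float
    present: bool | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is None:
        return "," if Path(path).suffix.lower() == ".csv" else "\t"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_locus_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a per-locus table from TSV/CSV.

    Missing values may be encoded as ``n.a.``, ``NA`` or an empty cell; all
    are normalised to NaN (or ``<NA>`` for the integer phylostratum).  Row
    order is preserved.

    Raises
    ------
    ValueError
        If a required column is absent, a ``locus_id`` is duplicated (the
        error names the id), or a numeric cell cannot be parsed (the error
        gives the 1-based data row number).
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table {path} lacks required columns {missing}")
    df = df[LOCUS_COLUMNS].copy()
    for col in ("ka", "ks", "omega", "ps", "order_index"):
        raw = df[col].str.strip()
        raw = raw.where(~raw.isin(NA_MARKERS), other=np.nan)
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(
                f"unparseable numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at data row {row} of {path}"
            )
        df[col] = parsed
    dup = df["locus_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate locus_id {df['locus_id'][dup].iloc[0]!r} in {path}")
    df["ps"] = df["ps"].astype("Int64")
    ps_vals = df["ps"].dropna()
    if len(ps_vals) and ((ps_vals < 1) | (ps_vals > 13)).any():
        raise ValueError("phylostratum values must lie in [1, 13]")
    if df["order_index"].notna().any():
        df["order_index"] = df["order_index"].astype("Int64")
    unknown = set(df["comparison"].dropna()) - set(COMPARISONS) - set(NA_MARKERS)
    if unknown:
        raise ValueError(f"unknown comparison labels {sorted(unknown)}")
    return df.reset_index(drop=True)


def write_locus_table(df: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a locus table; missing values are encoded as ``n.a.``."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df[LOCUS_COLUMNS].to_csv(path, sep=sep, index=False, na_rep="n.a.")


def read_expression_table(
    path: str | Path,
    assay: str,
    layout: str = "wide",
    dialect: str | None = None,
) -> pd.DataFrame:
    """Read expression measurements for one assay.

    ``layout="wide"`` expects a ``locus_id`` column plus one column per
    sample; the matrix is melted to long (locus, sample) rows.  Empty cells
    become abundance 0 with the present call left missing.
    ``layout="long"`` expects columns ``locus_id, sample_id, abundance``
    and optionally ``present``; if the file carries an ``assay`` column
    only rows matching the requested assay are kept.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    path = Path(path)
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(
        path, sep=sep, na_values=list(NA_MARKERS), keep_default_na=True,
        low_memory=False,
    )
    if layout == "wide":
        if "locus_id" not in raw.columns:
            raise ValueError("wide expression table needs a locus_id column")
        long = raw.melt(id_vars="locus_id", var_name="sample_id", value_name="abundance")
        long["abundance"] = long["abundance"].fillna(0.0).astype(float)
        long["present"] = pd.array([pd.NA] * len(long), dtype="boolean")
    elif layout == "long":
        need = {"locus_id", "sample_id", "abundance"}
        if not need <= set(raw.columns):
            raise ValueError(f"long expression table needs columns {sorted(need)}")
        long = raw.copy()
        if "assay" in long.columns:
            long = long[long["assay"] == assay].reset_index(drop=True)
            if long.empty:
                raise ValueError(f"no rows for assay {assay!r} in {path}")
        long["abundance"] = long["abundance"].fillna(0.0).astype(float)
        if "present" in long.columns:
            col = long["present"]
            if col.dtype == object:  # serialized True/False strings
                col = col.map({"True": True, "False": False, True: True, False: False})
            long["present"] = col.astype("boolean")
        else:
            long["present"] = pd.array([pd.NA] * len(long), dtype="boolean")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if (long["abundance"] < 0).any():
        raise ValueError("negative abundance encountered")
    long["assay"] = assay
    long = long[["locus_id", "sample_id", "assay", "abundance", "present"]]
    if long.duplicated(["locus_id", "sample_id", "assay"]).any():
        raise ValueError("duplicate (locus_id, sample_id, assay) rows")
    return long.reset_index(drop=True)


def write_expression_table(df: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a long-format expression table."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df.to_csv(path, sep=sep, index=False, na_rep="n.a.")


def join_analysis_table(
    loci: pd.DataFrame,
    expression: pd.DataFrame,
    n_samples: int = 11,
) -> pd.DataFrame:
    """Join loci with per-assay abundance totals and breadth counts.

    Produces one row per input locus; loci without any expression record get
    total abundance 0 and breadth 0 for every assay observed in
    ``expression``.  Expression rows whose locus is not in ``loci`` are
    logged and dropped; an empty intersection is an error, as are duplicate
    (locus, sample, assay) measurements.
    """
    if expression.duplicated(["locus_id", "sample_id", "assay"]).any():
        raise ValueError("duplicate (locus_id, sample_id, assay) measurements")
    known = set(loci["locus_id"])
    matched = expression[expression["locus_id"].isin(known)]
    n_dropped = len(expression) - len(matched)
    if n_dropped:
        orphans = sorted(set(expression["locus_id"]) - known)
        logger.warning(
            "dropping %d expression rows for %d unmatched loci (e.g. %s)",
            n_dropped, len(orphans), orphans[:3],
        )
    if len(expression) and matched.empty:
        raise ValueError("no expression locus_id matches the locus table")
    out = loci.copy().reset_index(drop=True)
    for assay, grp in matched.groupby("assay"):
        n_obs = grp["sample_id"].nunique()
        if n_obs > n_samples:
            raise ValueError(
                f"assay {assay!r} has {n_obs} samples but n_samples={n_samples}"
            )
        gea = grp.groupby("locus_id")["abundance"].sum()
        geb = grp.groupby("locus_id")["present"].apply(
            lambda s: int((s == True).sum())  # noqa: E712 -- nullable boolean
        )
        out[f"gea_{assay}"] = out["locus_id"].map(gea).fillna(0.0)
        out[f"geb_{assay}"] = out["locus_id"].map(geb).fillna(0).astype(int)
    return out


def records_to_frame(records: Iterable[LocusRecord]) -> pd.DataFrame:
    """Convert LocusRecord objects to a canonical locus table."""
    rows = [
        (r.locus_id, r.chromosome, r.order_index, r.ka, r.ks, r.omega, r.ps, r.comparison)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    df["ps"] = df["ps"].astype("Int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[LocusRecord]:
    """Convert a locus table to LocusRecord objects."""
    out = []
    for row in df.itertuples(index=False):
        ps = None if pd.isna(row.ps) else int(row.ps)
        out.append(
            LocusRecord(
                locus_id=row.locus_id,
                chromosome=str(row.chromosome),
                order_index=int(row.order_index),
                ka=float(row.ka) if pd.notna(row.ka) else np.nan,
                ks=float(row.ks) if pd.notna(row.ks) else np.nan,
                omega=float(row.omega) if pd.notna(row.omega) else np.nan,
                ps=ps,
                comparison=row.comparison,
            )
        )
    return out
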