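"""Codon-level Ka/Ks estimation (Nei–Gojobori 1986 counting with a
Jukes–Cantor multiple-hit correction), ortholog best-pair selection and
the quality-control filters applied before any downstream analysis.

The estimator follows the classic NG86 recipe:

* every position of each sense codon contributes a fractional synonymous
  site count s = (# synonymous single-nucleotide mutants at the position)/3,
  with mutations to stop codons counted as nonsynonymous;
* observed differences between two codons are decomposed over all minimal
  mutational pathways (orderings of the differing positions), equally
  weighted; pathways passing through a stop codon are excluded and the
  weights renormalised (if every pathway is excluded, all are kept);
* proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
  d = -(3/4)·ln(1 - (4/3)·p), which is undefined for p >= 3/4.

ω = Ka/Ks is reported when both rates are defined and Ks > 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO import parse as seqio_parse

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonPair",
    "KaKsResult",
    "HitRecord",
    "codon_site_counts",
    "pathway_diffs",
    "kaks_pair",
    "jukes_cantor",
    "read_fasta_pairs",
    "select_ortholog_pairs",
    "apply_qc_filters",
    "kaks_table",
]

_BASES = "ACGT"
#: codon -> amino acid, standard genetic code
CODON_TABLE: Mapping[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TABLE))


@dataclass(frozen=True)
class CodonPair:
    """A pair of aligned coding sequences (equal length, multiple of 3)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) % 3:
            raise ValueError("aligned length must be a multiple of 3")
        bad = set(a + b) - set("ACGTN-")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class KaKsResult:
    """Site/difference counts and corrected rates for one aligned pair."""

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ka: float
    ks: float
    omega: float
    n_codons_used: int


@dataclass(frozen=True)
class HitRecord:
    """One protein similarity-search hit (query vs subject)."""

    query_id: str
    subject_id: str
    identity_pct: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    if codon not in CODON_TABLE:
        raise ValueError(f"{codon!r} is not an unambiguous sense codon")
    return codon


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Each position contributes (# synonymous single-nucleotide mutants)/3
    synonymous sites; mutants that create a stop codon count as
    nonsynonymous.  The two counts always sum to 3.
    """
    codon = _check_sense(codon)
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TABLE.get(mutant) == aa:  # stops are absent from the table
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts between two codons.

    All minimal mutational pathways (orderings of the differing positions)
    are weighted equally; pathways through a stop codon are excluded and
    the remaining weights renormalised.  If every pathway passes through a
    stop, all pathways are kept with equal weight.
    """
    codon_a = _check_sense(codon_a)
    codon_b = _check_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (sd, nd, hits_stop)
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                hits_stop = True
                nd += 1.0  # step into a stop treated as nonsynonymous
            elif CODON_TABLE[nxt] == CODON_TABLE.get(cur, None):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, hits_stop))
    usable = [p for p in paths if not p[2]]
    if not usable:
        usable = paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4)·ln(1 - (4/3)p); NaN for p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def kaks_pair(pair: CodonPair) -> KaKsResult:
    """NG86 Ka/Ks estimate for one aligned codon pair.

    Codon columns containing a gap or N in either sequence are dropped from
    both.  Site counts are averaged over the two sequences; rates with
    p >= 3/4 (or a zero site count) are undefined (NaN); ω is defined only
    when both rates are and Ks > 0.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    used = 0
    for ca, cb in pair.codons():
        if set(ca + cb) - set(_BASES):
            continue  # gap or N in this codon column
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, _ = codon_site_counts(ca)
        sb, _ = codon_site_counts(cb)
        ds, dn = pathway_diffs(ca, cb)
        s_a += sa
        s_b += sb
        sd += ds
        nd += dn
        used += 1
    if used == 0:
        raise ValueError("no usable codons in alignment")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * used - s_sites
    ks = jukes_cantor(sd / s_sites) if s_sites > 0 else math.nan
    ka = jukes_cantor(nd / n_sites) if n_sites > 0 else math.nan
    if math.isnan(ka) or math.isnan(ks) or ks <= 0:
        omega = math.nan
    else:
        omega = ka / ks
    return KaKsResult(s_sites, n_sites, sd, nd, ka, ks, omega, used)


def read_fasta_pairs(
    path: str | Path, match: str = "order"
) -> list[tuple[str, str, CodonPair]]:
    """Read aligned CDS pairs from FASTA.

    ``match="order"`` pairs consecutive records (1st with 2nd, ...);
    ``match="prefix"`` pairs records sharing the id prefix before the last
    ``|`` or ``_`` separator.
    """
    records = list(seqio_parse(str(path), "fasta"))
    if match == "order":
        if len(records) % 2:
            raise ValueError("order-matched FASTA needs an even record count")
        it = iter(records)
        pairs = [(a, b) for a, b in zip(it, it)]
    elif match == "prefix":
        groups: dict[str, list] = {}
        for rec in records:
            key = rec.id.rsplit("|", 1)[0] if "|" in rec.id else rec.id.rsplit("_", 1)[0]
            groups.setdefault(key, []).append(rec)
        bad = {k: len(v) for k, v in groups.items() if len(v) != 2}
        if bad:
            raise ValueError(f"prefix groups without exactly two records: {bad}")
        pairs = [tuple(v) for _, v in sorted(groups.items())]
    else:
        raise ValueError(f"unknown match mode {match!r}")
    return [(a.id, b.id, CodonPair(str(a.seq), str(b.seq))) for a, b in pairs]


def select_ortholog_pairs(
    hits: Sequence[HitRecord] | pd.DataFrame,
    evalue_max: float = 1e-5,
    identity_min: float = 90.0,
) -> dict[str, str]:
    """One-to-one best-pair selection from a similarity hit table.

    Hits with E-value above ``evalue_max`` or identity below
    ``identity_min`` are discarded.  Per query the best hit is kept
    (maximum bitscore, then minimum E-value, then lexicographically
    smallest subject id); then per subject only its best query survives,
    by the same ordering, so the final mapping is one-to-one.
    """
    if isinstance(hits, pd.DataFrame):
        hits = [
            HitRecord(r.query_id, r.subject_id, r.identity_pct, r.evalue, r.bitscore)
            for r in hits.itertuples(index=False)
        ]
    kept = [h for h in hits if h.evalue <= evalue_max and h.identity_pct >= identity_min]

    def rank(h: HitRecord) -> tuple:
        return (-h.bitscore, h.evalue, h.subject_id)

    best_per_query: dict[str, HitRecord] = {}
    for h in kept:
        cur = best_per_query.get(h.query_id)
        if cur is None or rank(h) < rank(cur):
            best_per_query[h.query_id] = h

    def qrank(h: HitRecord) -> tuple:
        return (-h.bitscore, h.evalue, h.query_id)

    best_per_subject: dict[str, HitRecord] = {}
    for h in best_per_query.values():
        cur = best_per_subject.get(h.subject_id)
        if cur is None or qrank(h) < qrank(cur):
            best_per_subject[h.subject_id] = h
    return {h.query_id: h.subject_id for h in best_per_subject.values()}


def apply_qc_filters(
    records: pd.DataFrame,
    ka_max: float = 1.0,
    ks_max: float = 5.0,
    drop_zero_or_na: bool = True,
    ks_trim_alpha: float | None = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-control filtering of a per-locus Ka/Ks table.

    Removes rows with Ka > ``ka_max`` or Ks > ``ks_max``; optionally rows
    where Ka or Ks is zero or missing; then trims the Ks distribution
    symmetrically at level ``ks_trim_alpha`` (rows strictly below the α/2
    or strictly above the 1−α/2 empirical quantile are removed; pass None
    or 0 to skip).  Returns the surviving rows and a per-rule removal log.
    """
    log: dict[str, int] = {}
    df = records.copy()
    n0 = len(df)
    if drop_zero_or_na:
        bad = df["ka"].isna() | df["ks"].isna() | (df["ka"] == 0) | (df["ks"] == 0)
        log["zero_or_na"] = int(bad.sum())
        df = df[~bad]
    bad = df["ka"] > ka_max
    log["ka_gt_max"] = int(bad.sum())
    df = df[~bad]
    bad = df["ks"] > ks_max
    log["ks_gt_max"] = int(bad.sum())
    df = df[~bad]
    if ks_trim_alpha:
        if not len(df):
            raise ValueError("all rows removed before the Ks trim")
        lo = df["ks"].quantile(ks_trim_alpha / 2.0)
        hi = df["ks"].quantile(1.0 - ks_trim_alpha / 2.0)
        bad = (df["ks"] < lo) | (df["ks"] > hi)
        log["ks_trim"] = int(bad.sum())
        df = df[~bad]
    if not len(df):
        raise ValueError("quality-control filters removed every row")
    log["kept"] = len(df)
    log["input"] = n0
    return df.reset_index(drop=True), log


def kaks_table(pairs: Iterable[tuple[str, str, CodonPair]]) -> pd.DataFrame:
    """Estimate Ka/Ks for many aligned pairs, one row per pair."""
    rows = []
    for qid, sid, pair in pairs:
        r = kaks_pair(pair)
        rows.append(
            (qid, sid, r.s_sites, r.n_sites, r.sd, r.nd, r.ka, r.ks, r.omega, r.n_codons_used)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "s_sites", "n_sites", "sd", "nd",
            "ka", "ks", "omega", "n_codons_used",
        ],
    )
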