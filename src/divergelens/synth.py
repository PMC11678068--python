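"""Synthetic genomes, expression matrices and codon-pair evolution.

The generator emits data with the statistical structure the downstream
analyses assume, so the whole pipeline can be exercised and calibrated
without any external download:

* Ks is i.i.d. normal truncated to (0, 5] — approximately normal, the
  neutral-rate proxy, statistically independent of expression by
  construction;
* ω is lognormal (right-skewed) with a mild increase in gene age class
  (younger phylostrata evolve faster); a small fraction of loci are
  forced anchors with ω > 1 (positive selection), and ω at flanking loci
  is inflated by a triangular kernel decaying with ordinal distance — the
  hitchhiking signature;
* Ka is defined as ω·Ks, keeping the emitted table internally consistent;
* log10 expression abundance decreases linearly in the ω rank and in the
  phylostratum, plus Gaussian noise; per-sample presence is Bernoulli
  with probability increasing in abundance rank, so breadth tracks
  abundance; the total abundance is split across present samples and EST
  counts are Poisson in the per-sample abundance.

Every random draw flows through one seeded generator, so a fixed seed
reproduces the tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .kaks import CODON_TABLE, SENSE_CODONS, STOP_CODONS, CodonPair

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_genome",
    "generate_expression",
    "evolve_codon_pair",
]

#: Gene-age class frequencies, oldest (1) to youngest (13): most genes
#: trace back to ancient strata, with a long tail of young classes.
DEFAULT_PS_PROBS = (
    0.25, 0.12, 0.10, 0.08, 0.07, 0.06, 0.06, 0.05, 0.05, 0.05, 0.04, 0.04, 0.03,
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic genome and expression generator."""

    n_loci: int = 20_000
    n_chromosomes: int = 5
    n_samples: int = 11
    ps_probs: tuple = DEFAULT_PS_PROBS
    ks_mean: float = 0.22          # truncated-normal Ks location (interspecies scale)
    ks_sd: float = 0.08
    omega_logmean: float = -1.7    # lognormal base-ω: median ~0.18
    omega_logsd: float = 0.6
    ps_omega_slope: float = 0.9    # added to log ω, scaled by (ps-1)/12
    anchor_rate: float = 0.0165    # fraction of loci forced ω > 1
    hitch_amplitude: float = 0.15  # ω added at distance 0 from an anchor
    hitch_range: int = 15          # kernel reaches all default bands
    gea_intercept: float = 2.5     # log10 total abundance at rank-0 covariates
    gea_omega_slope: float = 2.0   # per unit rank01(ω)
    gea_ps_slope: float = 1.0      # per unit (ps-1)/12
    gea_noise_sd: float = 0.8
    breadth_steepness: float = 6.0 # logistic slope of per-sample presence
    breadth_pivot: float = 0.35    # abundance rank with presence prob 1/2
    est_scale: float = 0.3         # EST Poisson rate per unit abundance
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.ps_probs, dtype=float)
        if len(probs) != 13 or probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("ps_probs must be 13 nonnegative values summing to 1")
        if self.n_loci < self.n_chromosomes:
            raise ValueError("need n_loci >= n_chromosomes")
        for name in ("anchor_rate",):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("ks_sd", "omega_logsd", "ps_omega_slope", "hitch_amplitude",
                     "gea_omega_slope", "gea_ps_slope", "gea_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SynthTruth:
    """Realised ground truth of one generated genome."""

    anchor_ids: list
    base_omega: np.ndarray
    hitch_added: np.ndarray
    gea_coefficients: dict
    log10_gea: np.ndarray | None = None
    presence: np.ndarray | None = None  # (n_loci, n_samples) boolean


def _rank01(v: np.ndarray) -> np.ndarray:
    """Ranks mapped to [0, 1] (average ranks for ties)."""
    r = stats.rankdata(v)
    return (r - 1) / max(len(v) - 1, 1)


def generate_genome(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate a per-locus table with Ks, ω, Ka, phylostratum and position."""
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    # loci spread over chromosomes in order, sizes equal up to one
    sizes = np.full(config.n_chromosomes, n // config.n_chromosomes)
    sizes[: n % config.n_chromosomes] += 1
    chrom = np.repeat([f"chr{i + 1}" for i in range(config.n_chromosomes)], sizes)
    order_index = np.concatenate([np.arange(s) for s in sizes])

    ps = rng.choice(np.arange(1, 14), size=n, p=np.asarray(config.ps_probs))
    a = (0.0 - config.ks_mean) / config.ks_sd
    b = (5.0 - config.ks_mean) / config.ks_sd
    ks = stats.truncnorm.rvs(
        a, b, loc=config.ks_mean, scale=config.ks_sd, size=n, random_state=rng
    )

    loc = config.omega_logmean + config.ps_omega_slope * (ps - 1) / 12.0
    log_omega = loc + rng.normal(0.0, config.omega_logsd, n)
    base_omega = np.exp(log_omega)

    is_anchor = rng.random(n) < config.anchor_rate
    if is_anchor.any() and config.omega_logsd > 0:
        # resample anchors from the upper tail of their own lognormal, ω > 1
        lo = stats.norm.cdf(0.0, loc=loc[is_anchor], scale=config.omega_logsd)
        u = lo + (1 - lo) * rng.random(is_anchor.sum())
        base_omega[is_anchor] = np.exp(
            stats.norm.ppf(u, loc=loc[is_anchor], scale=config.omega_logsd)
        )
    omega = base_omega.copy()

    # triangular hitchhiking kernel around anchors, within chromosomes
    hitch = np.zeros(n)
    if config.hitch_amplitude > 0 and is_anchor.any():
        start = 0
        for s in sizes:
            sl = slice(start, start + s)
            apos = np.flatnonzero(is_anchor[sl])
            if len(apos):
                pos = np.arange(s)
                dist = np.abs(pos[:, None] - apos[None, :]).min(axis=1).astype(float)
                add = config.hitch_amplitude * np.maximum(0.0, 1.0 - dist / config.hitch_range)
                add[dist == 0] = 0.0  # anchors keep their forced ω
                hitch[sl] = add
            start += s
    omega = omega + hitch

    locus_ids = np.array([f"SYNT{i:05d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chromosome": chrom,
            "order_index": order_index,
            "ka": omega * ks,
            "ks": ks,
            "omega": omega,
            "ps": ps,
            "comparison": "interspecies",
        }
    )
    df["ps"] = df["ps"].astype("Int64")
    truth = SynthTruth(
        anchor_ids=list(locus_ids[is_anchor]),
        base_omega=base_omega,
        hitch_added=hitch,
        gea_coefficients={
            "intercept": config.gea_intercept,
            "omega_slope": config.gea_omega_slope,
            "ps_slope": config.gea_ps_slope,
            "noise_sd": config.gea_noise_sd,
        },
    )
    return df, truth


def generate_expression(
    loci: pd.DataFrame, truth: SynthTruth, config: SynthConfig
) -> pd.DataFrame:
    """Generate long-format expression records coupled to the genome.

    Emits three assays per locus over ``n_samples`` samples: ``rnaseq_rpm``
    (abundance split over present samples), ``est`` (Poisson counts) and
    ``microarray`` (scaled signal with the generative present call filled,
    standing in for externally preprocessed calls).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(loci)
    omega = loci["omega"].to_numpy(dtype=float)
    ps = loci["ps"].to_numpy(dtype=float)
    log10_gea = (
        config.gea_intercept
        - config.gea_omega_slope * _rank01(omega)
        - config.gea_ps_slope * (ps - 1) / 12.0
        + rng.normal(0.0, config.gea_noise_sd, n)
    )
    total = np.power(10.0, log10_gea)

    # per-sample presence: probability rises with abundance rank; a locus
    # with low abundance is present in few samples (high specificity)
    arank = _rank01(log10_gea)
    p_present = 1.0 / (1.0 + np.exp(-config.breadth_steepness * (arank - config.breadth_pivot)))
    presence = rng.random((n, config.n_samples)) < p_present[:, None]

    # split the total abundance across present samples (uniform Dirichlet)
    shares = rng.gamma(1.0, 1.0, size=(n, config.n_samples))
    shares[~presence] = 0.0
    row_sum = shares.sum(axis=1, keepdims=True)
    np.divide(shares, row_sum, out=shares, where=row_sum > 0)
    rpm = shares * total[:, None]

    est = rng.poisson(config.est_scale * rpm)
    signal = rpm * 300.0 * np.exp(rng.normal(0.0, 0.1, size=rpm.shape))
    signal[~presence] = 0.0

    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    locus_rep = np.repeat(loci["locus_id"].to_numpy(), config.n_samples)
    sample_rep = np.tile(samples, n)
    na = pd.array([pd.NA] * (n * config.n_samples), dtype="boolean")
    frames = [
        pd.DataFrame(
            {
                "locus_id": locus_rep,
                "sample_id": sample_rep,
                "assay": "rnaseq_rpm",
                "abundance": rpm.ravel(),
                "present": na,
            }
        ),
        pd.DataFrame(
            {
                "locus_id": locus_rep,
                "sample_id": sample_rep,
                "assay": "est",
                "abundance": est.ravel().astype(float),
                "present": na,
            }
        ),
        pd.DataFrame(
            {
                "locus_id": locus_rep,
                "sample_id": sample_rep,
                "assay": "microarray",
                "abundance": signal.ravel(),
                "present": pd.array(presence.ravel(), dtype="boolean"),
            }
        ),
    ]
    truth.log10_gea = log10_gea
    truth.presence = presence
    return pd.concat(frames, ignore_index=True)


_SYN_NEIGHBOURS: dict[str, list] = {}
_NONSYN_NEIGHBOURS: dict[str, list] = {}
for _codon in SENSE_CODONS:
    syn, nonsyn = [], []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _b + _codon[_pos + 1 :]
            if _mut in STOP_CODONS:
                continue
            (syn if CODON_TABLE[_mut] == CODON_TABLE[_codon] else nonsyn).append(_mut)
    _SYN_NEIGHBOURS[_codon] = syn
    _NONSYN_NEIGHBOURS[_codon] = nonsyn


def evolve_codon_pair(
    n_codons: int,
    n_syn_events: int,
    n_nonsyn_events: int,
    seed: int,
    max_tries: int = 10_000,
) -> CodonPair:
    """Evolve one sequence copy by a fixed number of substitution events.

    A random sense-codon ancestor is copied and mutated by exactly
    ``n_syn_events`` synonymous and ``n_nonsyn_events`` nonsynonymous
    single-nucleotide substitutions, in random interleaved order, never
    creating a stop codon.  Events are placed by rejection sampling over
    codon positions; an infeasible demand errors after ``max_tries``.
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    rng = np.random.default_rng(seed)
    ancestor = list(rng.choice(SENSE_CODONS, size=n_codons))
    derived = list(ancestor)
    events = ["syn"] * n_syn_events + ["nonsyn"] * n_nonsyn_events
    rng.shuffle(events)
    for kind in events:
        table = _SYN_NEIGHBOURS if kind == "syn" else _NONSYN_NEIGHBOURS
        for _ in range(max_tries):
            i = int(rng.integers(n_codons))
            choices = table[derived[i]]
            if choices:
                derived[i] = choices[int(rng.integers(len(choices)))]
                break
        else:
            raise ValueError(f"could not place a {kind} event after {max_tries} tries")
    return CodonPair("".join(ancestor), "".join(derived))
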