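"""End-to-end orchestration: configuration, the full analysis run, and
report assembly.

A run takes a per-locus table plus expression records (either read from
files or freshly simulated), applies the quality-control filters, builds
the joined analysis table and then executes the analyses: abundance
windows, the normal-approximation shape test on Ks, the hitchhiking
proximity test, window-level correlation smoothing with the dependent-
correlation permutation test, and incidence/breadth summaries.  Outputs
are TSV/JSON files plus a run log recording inputs, seed and filter
counts, so a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlations import perm_corr_diff_test, correlation_matrices
from .distshape import norm_approx_test
from .expression import gea_tertiles, gea_windows, geb_counts, classify_breadth, present_calls
from .hitchhike import DEFAULT_BANDS, assign_bands, compare_bands, flag_positive, parse_bands
from .kaks import apply_qc_filters
from .summaries import group_profile, incidence_by_group, chromosome_summary
from .synth import SynthConfig, generate_expression, generate_genome
from .tables import join_analysis_table, read_expression_table, read_locus_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """One analysis run: inputs, analysis constants and the seed.

    Defaults carry the analysis constants used throughout: windows of 100
    loci, 30 shape-test partitions, bands 1-5/6-10/11-15, smoothing over
    100 neighbours, a 100,000-pattern permutation cap, ω > 1 positive-
    selection flagging, 1 RPM present calls, Ka ≤ 1 / Ks ≤ 5 retention and
    a symmetric 5% Ks trim.
    """

    locus_table: str | None = None
    expression_table: str | None = None
    assay: str = "rnaseq_rpm"
    n_samples: int = 11
    window: int = 100
    k_partitions: int = 30
    bands: str = "1-5,6-10,11-15"
    m_neighbors: int = 100
    perm_cap: int = 100_000
    omega_positive: float = 1.0
    rpm_threshold: float = 1.0
    ka_max: float = 1.0
    ks_max: float = 5.0
    ks_trim_alpha: float = 0.05
    simulate: bool = False
    synth_n_loci: int | None = None
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _load_inputs(config: RunConfig):
    if config.simulate or config.locus_table is None:
        kwargs = {"seed": config.seed}
        if config.synth_n_loci is not None:
            kwargs["n_loci"] = config.synth_n_loci
        synth = SynthConfig(**kwargs)
        loci, truth = generate_genome(synth)
        expression = generate_expression(loci, truth, synth)
        return loci, expression
    loci = read_locus_table(config.locus_table)
    expression = read_expression_table(config.expression_table, config.assay)
    return loci, expression


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute filters → metrics → analyses and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci, expression = _load_inputs(config)

    filtered, filter_log = apply_qc_filters(
        loci,
        ka_max=config.ka_max,
        ks_max=config.ks_max,
        ks_trim_alpha=config.ks_trim_alpha,
    )
    expression = present_calls(expression, rpm_threshold=config.rpm_threshold)
    table = join_analysis_table(filtered, expression, n_samples=config.n_samples)
    geb = geb_counts(expression, config.assay, n_samples=config.n_samples)
    table["geb"] = table["locus_id"].map(geb).fillna(0).astype(int)
    table["breadth_class"] = classify_breadth(table["geb"])
    table["gea_tertile"] = gea_tertiles(table, config.assay)
    table.to_csv(out / "analysis_table.tsv", sep="\t", index=False, na_rep="n.a.")

    windows = gea_windows(table, config.assay, window=config.window)
    windows.to_csv(out / "gea_windows.tsv", sep="\t", index=False)

    shape = norm_approx_test(
        filtered["ks"].to_numpy(dtype=float), config.k_partitions, seed=config.seed
    )

    anchors = flag_positive(filtered)
    bands = parse_bands(config.bands)
    assignments = assign_bands(filtered, anchors, bands)
    band_table = compare_bands(assignments, filtered, bands)
    band_table.to_csv(out / "proximity_bands.tsv", sep="\t", index=False)

    perm = perm_corr_diff_test(
        windows["mean_ks"].to_numpy(),
        windows["mean_omega"].to_numpy(),
        windows["mean_log10_gea"].to_numpy(),
        cap=config.perm_cap,
        seed=config.seed,
    )
    old_cor, new_cor = correlation_matrices(
        table["ks"].to_numpy(dtype=float),
        table["omega"].to_numpy(dtype=float),
        np.log10(np.clip(table[f"gea_{config.assay}"].to_numpy(dtype=float), 1e-12, None)),
        m=min(config.m_neighbors, len(table)),
    )

    incidence = incidence_by_group(table, table["gea_tertile"])
    incidence["table"].to_csv(out / "incidence_by_tertile.tsv", sep="\t", index=False)
    breadth_profile = group_profile(
        table, table["breadth_class"], value="ps",
        order=["not_expressed", "specific", "broad"],
    )
    breadth_profile["table"].to_csv(out / "ps_by_breadth.tsv", sep="\t", index=False)
    chrom = chromosome_summary(table)
    chrom["table"].to_csv(out / "chromosome_summary.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "filter_log": filter_log,
        "n_loci_analyzed": int(len(table)),
        "n_windows": int(len(windows)),
        "ks_shape_test": {"statistic": shape.statistic, "df": shape.df, "p": shape.p},
        "n_positive": int(len(anchors)),
        "band_means": {
            r["band"]: r["mean_omega"] for _, r in band_table.iterrows()
        },
        "perm_test": {
            "cor_ks_gea": perm.cor_xz,
            "cor_omega_gea": perm.cor_yz,
            "diff": perm.diff,
            "p": perm.p,
            "n_perm": perm.n_perm,
            "exhaustive": perm.exhaustive,
        },
        "raw_cor": np.asarray(old_cor).tolist(),
        "smoothed_cor": np.asarray(new_cor).tolist(),
        "incidence": {
            "chi2": incidence["chi2"],
            "df": incidence["df"],
            "p": incidence["p"],
            "fractions": dict(
                zip(incidence["table"]["group"], incidence["table"]["fraction"])
            ),
        },
        "ps_by_breadth_anova_p": breadth_profile["anova_p"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d loci, %d windows", len(table), len(windows))
    return report
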