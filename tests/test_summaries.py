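import numpy as np
import pandas as pd
import pytest

import divergelens as dl
from divergelens.tables import records_to_frame


def loci_with_omega(omegas, chrom="chr1", ks=0.2):
    return records_to_frame(
        [
            dl.LocusRecord(f"{chrom}_{i:04d}", chrom, i, ka=w * ks, ks=ks, omega=w, ps=1)
            for i, w in enumerate(omegas)
        ]
    )


class TestIncidenceByGroup:
    def test_two_by_two_statistic(self):
        """5/50 vs 10/50 positives: hand-computed Pearson χ² = 1.9608, df 1."""
        omegas = [2.0] * 5 + [0.5] * 45 + [2.0] * 10 + [0.5] * 40
        loci = loci_with_omega(omegas)
        grouping = pd.Series(["g1"] * 50 + ["g2"] * 50, index=loci.index)
        res = dl.incidence_by_group(loci, grouping)
        assert res["chi2"] == pytest.approx(1.9608, abs=1e-4)
        assert res["df"] == 1
        tab = res["table"].set_index("group")
        assert tab.loc["g1", "n_positive"] == 5
        assert tab.loc["g2", "fraction"] == pytest.approx(0.2)

    def test_identical_incidence_gives_zero(self):
        omegas = ([2.0] * 5 + [0.5] * 45) * 2
        loci = loci_with_omega(omegas)
        grouping = pd.Series(["g1"] * 50 + ["g2"] * 50, index=loci.index)
        res = dl.incidence_by_group(loci, grouping)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(0)
        loci = loci_with_omega(rng.lognormal(-1.5, 0.8, 300))
        grouping = pd.Series(rng.choice(["a", "b", "c"], 300), index=loci.index)
        res = dl.incidence_by_group(loci, grouping)
        assert res["table"]["n_positive"].sum() == (loci["omega"] > 1).sum()

    def test_incidence_declines_with_abundance_on_default_genome(self, default_genome):
        table = default_genome["table"]
        tert = dl.gea_tertiles(table, "rnaseq_rpm")
        res = dl.incidence_by_group(table, tert)
        frac = res["table"].set_index("group")["fraction"]
        assert frac["low"] > frac["high"]
        assert res["p"] < 0.001


class TestGroupProfile:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=200)
        loci = loci_with_omega(np.abs(vals))
        grouping = pd.Series(["g1", "g2"] * 100, index=loci.index)
        res = dl.group_profile(loci, grouping, value="omega")
        letters = res["table"].set_index("group")["letters"]
        assert letters["g1"] == letters["g2"]

    def test_separated_groups_get_distinct_letters(self):
        loci = loci_with_omega([0.1] * 30 + [5.0] * 30)
        grouping = pd.Series(["lo"] * 30 + ["hi"] * 30, index=loci.index)
        res = dl.group_profile(loci, grouping, value="omega")
        letters = res["table"].set_index("group")["letters"]
        assert set(letters["lo"]) & set(letters["hi"]) == set()
        assert res["anova_p"] < 1e-10

    def test_specific_loci_are_younger_on_default_genome(self, default_genome):
        """Specifically expressed loci have a higher mean phylostratum
        (younger genes) than broadly expressed loci."""
        table = default_genome["table"]
        res = dl.group_profile(
            table, table["breadth_class"], value="ps",
            order=["not_expressed", "specific", "broad"],
        )
        tab = res["table"].set_index("group")
        assert tab.loc["specific", "mean"] > tab.loc["broad", "mean"]
        assert res["anova_p"] < 0.001

    def test_omega_declines_with_breadth_on_default_genome(self, default_genome):
        """Mean ω decreases from narrow to broad expression; across the full
        0..11 breadth ladder the trend is strongly monotone."""
        from scipy.stats import spearmanr

        table = default_genome["table"]
        means = table.groupby("geb")["omega"].mean()
        rho = spearmanr(means.index, means.to_numpy()).statistic
        assert rho < -0.9
        res = dl.group_profile(
            table, table["breadth_class"], value="omega",
            order=["not_expressed", "specific", "broad"],
        )
        tab = res["table"].set_index("group")
        assert tab.loc["specific", "mean"] > tab.loc["broad", "mean"]


class TestCompactLetterDisplay:
    def test_chain_structure(self):
        # a ~ b, b ~ c, but a != c: b shares letters with both
        p = pd.DataFrame(1.0, index=list("abc"), columns=list("abc"))
        p.loc["a", "c"] = p.loc["c", "a"] = 0.001
        p.loc["a", "b"] = p.loc["b", "a"] = 0.5
        p.loc["b", "c"] = p.loc["c", "b"] = 0.5
        letters = dl.compact_letter_display(list("abc"), p)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestChromosomeSummary:
    def test_hand_computed_means(self):
        loci = records_to_frame(
            [
                dl.LocusRecord("a", "chr1", 0, 0.02, 0.1, 0.2, 1),
                dl.LocusRecord("b", "chr1", 1, 0.08, 0.2, 0.4, 1),
                dl.LocusRecord("c", "chr1", 2, 0.18, 0.3, 0.6, 1),
                dl.LocusRecord("d", "chr2", 0, 0.04, 0.4, 0.1, 1),
                dl.LocusRecord("e", "chr2", 1, 0.15, 0.5, 0.3, 1),
                dl.LocusRecord("f", "chr2", 2, 0.30, 0.6, 0.5, 1),
            ]
        )
        res = dl.chromosome_summary(loci)
        tab = res["table"].set_index("chromosome")
        assert tab.loc["chr1", "mean_ks"] == pytest.approx(0.2)
        assert tab.loc["chr1", "mean_omega"] == pytest.approx(0.4)
        assert tab.loc["chr2", "mean_ks"] == pytest.approx(0.5)
        assert tab.loc["chr2", "mean_omega"] == pytest.approx(0.3)

    def test_homogeneous_chromosomes_rarely_differ(self):
        """With identical ω distributions across chromosomes the pairwise
        tests reject at roughly their nominal rate."""
        rej = total = 0
        for seed in range(60):
            rng = np.random.default_rng(500 + seed)
            frames = []
            for chrom in ("chr1", "chr2", "chr3"):
                frames.append(loci_with_omega(rng.lognormal(-1.5, 0.6, 200), chrom=chrom))
            loci = pd.concat(frames, ignore_index=True)
            p = dl.chromosome_summary(loci)["pairwise_p"]
            vals = p.to_numpy()[np.triu_indices(3, 1)]
            rej += (vals < 0.05).sum()
            total += len(vals)
        assert 0.02 <= rej / total <= 0.08

    def test_shifted_chromosome_detected(self):
        rng = np.random.default_rng(9)
        a = loci_with_omega(rng.lognormal(-1.5, 0.6, 500), chrom="chr1")
        b = loci_with_omega(rng.lognormal(-1.5, 0.6, 500) + 0.5, chrom="chr2")
        loci = pd.concat([a, b], ignore_index=True)
        p = dl.chromosome_summary(loci)["pairwise_p"]
        assert p.loc["chr1", "chr2"] < 0.01

    def test_single_chromosome_skips_tests(self):
        loci = loci_with_omega([0.1, 0.2, 0.3])
        res = dl.chromosome_summary(loci)
        assert res["pairwise_p"] is None

    def test_default_genome_chromosomes_are_homogeneous(self, default_genome):
        """ω is generated independently of chromosome, so per-chromosome
        means are near the genome mean and no pair differs significantly."""
        filtered = default_genome["filtered"]
        res = dl.chromosome_summary(filtered)
        genome_mean = filtered["omega"].mean()
        assert np.allclose(res["table"]["mean_omega"], genome_mean, rtol=0.1)
        off = res["pairwise_p"].to_numpy()[np.triu_indices(5, 1)]
        # at most a nominal-rate handful of the 10 pairwise tests reject
        assert (off < 0.05).sum() <= 2
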