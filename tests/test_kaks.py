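import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import divergelens as dl
from divergelens.kaks import SENSE_CODONS

from oracle_ng86 import SENSE, oracle_diffs, oracle_pair_counts, oracle_sites


class TestCodonSiteCounts:
    @pytest.mark.parametrize(
        "codon, s, n",
        [("TTT", 1 / 3, 8 / 3), ("ATG", 0.0, 3.0), ("CTT", 1.0, 2.0)],
    )
    def test_known_codons(self, codon, s, n):
        got_s, got_n = dl.codon_site_counts(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(n)

    def test_total_sites_over_code(self):
        """Every sense codon contributes s+n = 3, hence 183 over the code."""
        total = sum(sum(dl.codon_site_counts(c)) for c in SENSE_CODONS)
        assert total == pytest.approx(183.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            dl.codon_site_counts("TAA")

    def test_matches_oracle_on_every_sense_codon(self):
        for codon in SENSE:
            assert dl.codon_site_counts(codon) == pytest.approx(oracle_sites(codon))


class TestPathwayDiffs:
    @pytest.mark.parametrize(
        "a, b, sd, nd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTC", 1.0, 0.0),
            ("TTT", "GTA", 0.5, 1.5),
        ],
    )
    def test_known_pairs(self, a, b, sd, nd):
        assert dl.pathway_diffs(a, b) == pytest.approx((sd, nd))

    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    def test_symmetric_and_counts_conserved(self, a, b):
        """Symmetric in arguments; steps sum to the Hamming distance."""
        fwd = dl.pathway_diffs(a, b)
        rev = dl.pathway_diffs(b, a)
        assert fwd == pytest.approx(rev)
        hamming = sum(x != y for x, y in zip(a, b))
        assert fwd[0] + fwd[1] == pytest.approx(hamming)


class TestKaKsPair:
    def test_identical_sequences(self):
        r = dl.kaks_pair(dl.CodonPair("ATGAAA", "ATGAAA"))
        assert r.ka == 0 and r.ks == 0
        assert math.isnan(r.omega)

    def test_single_synonymous_difference(self):
        r = dl.kaks_pair(dl.CodonPair("TTT" * 10, "TTC" + "TTT" * 9))
        assert r.sd == pytest.approx(1.0)
        assert r.s_sites == pytest.approx(10 / 3)
        assert r.ks == pytest.approx(-0.75 * math.log(0.6))
        assert r.ka == 0.0
        assert r.omega == 0.0

    def test_gapped_codons_dropped_from_both(self):
        r = dl.kaks_pair(dl.CodonPair("ATG---AAA", "ATGAAAAAA"))
        assert r.n_codons_used == 2

    def test_all_gaps_is_an_error(self):
        with pytest.raises(ValueError, match="usable"):
            dl.kaks_pair(dl.CodonPair("---", "---"))

    def test_nonsynonymous_only_evolution_gives_zero_ks(self):
        pair = dl.evolve_codon_pair(300, 0, 12, seed=5)
        r = dl.kaks_pair(pair)
        assert r.ks == 0.0
        assert math.isnan(r.omega)
        assert r.ka > 0

    def test_matches_oracle_on_random_alignments(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(5, 40))
            a = "".join(rng.choice(SENSE_CODONS, n))
            b = "".join(rng.choice(SENSE_CODONS, n))
            r = dl.kaks_pair(dl.CodonPair(a, b))
            S, N, Sd, Nd, used = oracle_pair_counts(a, b)
            assert r.s_sites == pytest.approx(S, abs=1e-9)
            assert r.n_sites == pytest.approx(N, abs=1e-9)
            assert r.sd == pytest.approx(Sd, abs=1e-9)
            assert r.nd == pytest.approx(Nd, abs=1e-9)

    def test_rate_ratio_tracks_event_ratio(self):
        """Estimated Ks/Ka rises monotonically in the synonymous:nonsynonymous
        event ratio of the generating process (rank correlation > 0.9)."""
        from scipy.stats import spearmanr

        ratios, estimates = [], []
        for i, (n_syn, n_non) in enumerate([(5, 40), (10, 30), (20, 20), (30, 10), (40, 5)]):
            pair = dl.evolve_codon_pair(500, n_syn, n_non, seed=100 + i)
            r = dl.kaks_pair(pair)
            ratios.append(n_syn / n_non)
            estimates.append(r.ks / r.ka)
        rho = spearmanr(ratios, estimates).statistic
        assert rho > 0.9


class TestSelectOrthologPairs:
    def hit(self, q="q1", s="s1", ident=95.0, e=1e-10, bits=200.0):
        return dl.HitRecord(q, s, ident, e, bits)

    def test_single_passing_hit_kept(self):
        assert dl.select_ortholog_pairs([self.hit()]) == {"q1": "s1"}

    def test_best_bitscore_wins(self):
        hits = [self.hit(s="s1", bits=200.0), self.hit(s="s2", bits=150.0)]
        assert dl.select_ortholog_pairs(hits) == {"q1": "s1"}

    def test_identity_cutoff_is_inclusive_at_90(self):
        assert dl.select_ortholog_pairs([self.hit(ident=89.9)]) == {}
        assert dl.select_ortholog_pairs([self.hit(ident=90.0)]) == {"q1": "s1"}

    def test_evalue_cutoff(self):
        assert dl.select_ortholog_pairs([self.hit(e=1e-4)]) == {}

    def test_mapping_is_one_to_one(self):
        """A query whose best subject is claimed by a stronger query drops
        out entirely (its weaker hits are not revisited)."""
        hits = [
            self.hit(q="q1", s="s1", bits=300.0),
            self.hit(q="q2", s="s1", bits=250.0),
            self.hit(q="q2", s="s2", bits=100.0),
        ]
        out = dl.select_ortholog_pairs(hits)
        assert out == {"q1": "s1"}
        assert len(set(out.values())) == len(out)


class TestQcFilters:
    @staticmethod
    def frame(pairs):
        return pd.DataFrame(pairs, columns=["ka", "ks"])

    def test_rule_application(self):
        df = self.frame([(0.1, 0.2), (1.2, 0.3), (0.1, 6.0), (0.0, 0.1)])
        kept, log = dl.apply_qc_filters(df, ks_trim_alpha=None)
        assert len(kept) == 1
        assert kept.iloc[0].tolist() == [0.1, 0.2]
        assert log["ka_gt_max"] == 1 and log["ks_gt_max"] == 1 and log["zero_or_na"] == 1

    def test_published_rate_pairs_pass_bound_rules(self):
        """The worked per-locus rate values all survive the Ka<=1 / Ks<=5 /
        nonzero rules."""
        table1 = self.frame(
            [(0.0007, 0.0641), (0.0008, 0.0581), (0.0021, 0.1137),
             (0.0021, 0.0097), (0.0043, 0.0035)]
        )
        kept, _ = dl.apply_qc_filters(table1, ks_trim_alpha=None)
        assert len(kept) == 5

    def test_trim_removes_five_percent(self):
        rng = np.random.default_rng(0)
        df = self.frame(list(zip(rng.uniform(0.01, 0.9, 1000), rng.uniform(0.01, 4.9, 1000))))
        kept, log = dl.apply_qc_filters(df, ks_trim_alpha=0.05)
        assert len(kept) == 950
        assert log["ks_trim"] == 50

    def test_everything_removed_is_an_error(self):
        with pytest.raises(ValueError):
            dl.apply_qc_filters(self.frame([(1.5, 0.2), (0.0, 0.3)]), ks_trim_alpha=None)


class TestFastaPairs:
    def test_order_matching_round_trip(self, tmp_path):
        path = tmp_path / "pairs.fasta"
        path.write_text(">a1\nATGAAA\n>a2\nATGAAG\n>b1\nTTTTTC\n>b2\nTTCTTC\n")
        pairs = dl.read_fasta_pairs(path, match="order")
        assert [(q, s) for q, s, _ in pairs] == [("a1", "a2"), ("b1", "b2")]
        r = dl.kaks_pair(pairs[1][2])
        assert r.sd == pytest.approx(1.0)

    def test_odd_record_count_rejected(self, tmp_path):
        path = tmp_path / "odd.fasta"
        path.write_text(">a\nATG\n>b\nATG\n>c\nATG\n")
        with pytest.raises(ValueError, match="even"):
            dl.read_fasta_pairs(path, match="order")
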