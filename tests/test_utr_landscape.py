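"""UTR landscape: full-length flagging, k-mer enrichment, positional and
U-content profiles, Kozak matrix and UTR statistics."""

import numpy as np
import pytest

from mxpipe import utr_landscape as ul
from mxpipe.io_core import GeneModel, Interval, ValidationError
from mxpipe.synthetic_data import SynthesisSpec, make_genome
import pandas as pd


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "gene", "contig", "aln_start", "aln_end",
                       "polya_boundary"])


class TestFullLengthFlag:
    def _gene(self):
        return GeneModel("g1", "c1", "+", exons=[Interval(1, 500)],
                         cds=[Interval(101, 400)],
                         utr5=[Interval(1, 100)], utr3=[Interval(401, 500)],
                         partial=True)

    def test_exact_boundary_with_coverage_flagged(self):
        reads = _reads([("r1", "g1", "c1", 1, 500, 500)])
        assert ul.flag_full_length_3utr([self._gene()], reads) == {"g1"}

    def test_boundary_inside_utr_not_flagged(self):
        reads = _reads([("r1", "g1", "c1", 1, 500, 480)])
        assert ul.flag_full_length_3utr([self._gene()], reads,
                                        tolerance=5) == set()

    def test_partial_coverage_not_flagged(self):
        reads = _reads([("r1", "g1", "c1", 450, 500, 500)])
        assert ul.flag_full_length_3utr([self._gene()], reads) == set()

    def test_unknown_gene_rejected(self):
        reads = _reads([("r1", "ghost", "c1", 1, 500, 500)])
        with pytest.raises(ValidationError, match="ghost"):
            ul.flag_full_length_3utr([self._gene()], reads)

    def test_corpus_recovery_matches_manifest(self, corpus7):
        got = ul.flag_full_length_3utr(corpus7.models, corpus7.reads)
        assert got == set(corpus7.manifest["full_length_genes"])


class TestTerminalWindow:
    def test_long_utr_truncated_to_window(self):
        u = ul.UtrRecord("g", "three_prime", "A" * 312)
        [(tag, tail, short)] = ul.terminal_window([u])
        assert len(tail) == 100 and not short

    def test_short_utr_kept_whole_and_marked(self):
        u = ul.UtrRecord("g", "three_prime", "A" * 60)
        [(_, tail, short)] = ul.terminal_window([u])
        assert len(tail) == 60 and short

    def test_zero_window_rejected(self):
        with pytest.raises(ValidationError):
            ul.terminal_window([], window=0)


def _random_tails(rng, n=200, length=100, at=0.74):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return ["".join(rng.choice(list("ACGT"), size=length, p=p))
            for _ in range(n)]


def _plant(tails, motif, frac, rng, lo=20, hi=30):
    out = []
    for i, t in enumerate(tails):
        if i < frac * len(tails):
            off = int(rng.integers(lo, hi + 1))
            s = len(t) - off
            t = t[:s] + motif + t[s + len(motif):]
        out.append(t)
    return out


class TestKmerEnrichment:
    def test_dinucleotide_shuffle_preserves_doublets(self):
        from collections import Counter
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        sh = ul.dinucleotide_shuffle(seq, rng)
        assert sh != seq
        assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
        assert sh[0] == seq[0] and sh[-1] == seq[-1]

    def test_planted_hexamer_ranks_first(self):
        rng = np.random.default_rng(7)
        tails = _plant(_random_tails(rng), "AATAAA", 0.8, rng)
        res = ul.kmer_enrichment(tails, n_shuffles=100, seed=7)
        assert res[0].kmer == "AATAAA"
        assert res[0].z_score > 5

    def test_two_planted_motifs_both_in_top_three(self):
        rng = np.random.default_rng(7)
        tails = _random_tails(rng)
        half = len(tails) // 2
        tails = (_plant(tails[:half], "AATAAA", 0.8, rng)
                 + _plant(tails[half:], "AAATAA", 0.8, rng))
        res = ul.kmer_enrichment(tails, n_shuffles=100, seed=7)
        top3 = {r.kmer for r in res[:3]}
        assert {"AATAAA", "AAATAA"} <= top3

    def test_null_tails_separate_cleanly_from_planted_signal(self):
        """Without planting, the best of all 4096 k-mer z-scores stays far
        below what a planted motif reaches (computed null max ~4.9 here,
        versus >10 for an 80 % plant)."""
        rng = np.random.default_rng(7)
        tails = ["".join(rng.choice(list("ACGT"), size=100))
                 for _ in range(200)]
        res = ul.kmer_enrichment(tails, n_shuffles=100, seed=7)
        finite = [r.z_score for r in res if np.isfinite(r.z_score)]
        assert max(finite) < 6
        planted = ul.kmer_enrichment(
            _plant(tails, "AATAAA", 0.8, np.random.default_rng(7)),
            n_shuffles=100, seed=7)
        assert planted[0].kmer == "AATAAA"
        assert planted[0].z_score > 2 * max(finite)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValidationError):
            ul.kmer_enrichment(["ACGTACGT"] * 5)


class TestPositionalProfile:
    def test_fixed_offset_gives_point_mass(self):
        rng = np.random.default_rng(7)
        tails = _plant(_random_tails(rng), "AATAAA", 1.0, rng, lo=25, hi=25)
        prof = ul.positional_profile(tails, "AATAAA")
        assert prof.peak_position == -25

    def test_uniform_offset_window_recovered(self):
        rng = np.random.default_rng(7)
        tails = _plant(_random_tails(rng, n=400), "AATAAA", 1.0, rng)
        prof = ul.positional_profile(tails, "AATAAA")
        lo, hi = prof.half_window
        assert -30 <= lo <= hi <= -20

    def test_absent_kmer_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            prof = ul.positional_profile(["ACGT" * 25] * 30, "AAAAAA")
        assert all(v == 0 for v in prof.values)

    def test_values_are_probabilities(self, corpus7):
        from mxpipe.utr_landscape import extract_utrs, flag_full_length_3utr
        full = flag_full_length_3utr(corpus7.models, corpus7.reads)
        utrs = [u for u in extract_utrs(corpus7.models, corpus7.contigs)
                if u.kind == "three_prime" and u.gene_tag in full]
        tails = [t for _, t, _ in ul.terminal_window(utrs)]
        prof = ul.positional_profile(tails, "AATAAA")
        assert all(0 <= v <= 1 for v in prof.values)
        assert sum(prof.values) <= 1 + 1e-9  # one first-occurrence per seq


class TestUProfile:
    def test_all_a_is_zero(self):
        prof = ul.u_profile(["A" * 100] * 10)
        assert all(v == 0 for v in prof.values)

    def test_all_u_is_one(self):
        prof = ul.u_profile(["T" * 100])
        assert all(v == 1 for v in prof.values)

    def test_planted_flanks_elevate_u_content(self, corpus7):
        from mxpipe.utr_landscape import extract_utrs
        genes = corpus7.manifest["genes"]
        tails = [
            g["utr3_seq"][-100:] for g in genes.values()
            if g["polya_offset"] is not None
        ]
        prof = ul.u_profile(tails)
        vals = np.array(prof.values)
        # flank positions sit around the planted offsets (-30..-20 +- 10)
        flank = vals[100 - 40: 100 - 10]
        background = vals[0: 40]
        assert flank.mean() > background.mean() + 0.05


class TestKozak:
    def _gene(self, contig_seq_len=200):
        return GeneModel(
            "g1", "c1", "+", exons=[Interval(1, 60)],
            cds=[Interval(21, 56)], utr5=[Interval(1, 20)],
            utr3=[Interval(57, 60)], partial=True)

    def test_single_gene_one_hot(self):
        seq = "A" * 10 + "CCCCCCCCCC" + "ATG" + "G" * 33 + "TTTT"
        res = ul.kozak_matrix([self._gene()], {"c1": seq})
        assert res.n_used == 1
        col = res.matrix[1]   # first codon base
        assert col["A"] == 1.0
        assert (res.matrix.sum(axis=0) - 1.0).abs().max() < 1e-9

    def test_two_genes_half_half(self):
        seq1 = "C" * 20 + "ATG" + "G" * 33 + "TTTT"
        seq2 = "C" * 19 + "A" + "ATG" + "G" * 33 + "TTTT"
        g1 = self._gene()
        g2 = GeneModel("g2", "c2", "+", exons=[Interval(1, 60)],
                       cds=[Interval(21, 56)], utr5=[Interval(1, 20)],
                       utr3=[Interval(57, 60)], partial=True)
        res = ul.kozak_matrix([g1, g2], {"c1": seq1, "c2": seq2})
        assert res.matrix.loc["A", -1] == 0.5
        assert res.matrix.loc["C", -1] == 0.5

    def test_short_utr_excluded_and_counted(self):
        g = GeneModel("g1", "c1", "+", exons=[Interval(1, 45)],
                      cds=[Interval(6, 41)], utr5=[Interval(1, 5)],
                      partial=True)
        res = ul.kozak_matrix([g], {"c1": "A" * 45})
        assert res.n_used == 0 and res.n_excluded == 1

    def test_corpus_upstream_at_matches_generator(self, corpus7):
        res = ul.kozak_matrix(corpus7.models, corpus7.contigs)
        assert res.n_used > 50
        assert res.upstream_at_fraction == pytest.approx(
            corpus7.spec.utr5_at, abs=0.05)
        upstream_cols = [c for c in res.matrix.columns if c < 0]
        for c in upstream_cols:
            col = res.matrix[c]
            for base in "CG":
                assert col[base] < 0.4
        assert (res.matrix.sum(axis=0) - 1.0).abs().max() < 1e-9


class TestUtrStats:
    def test_mean_length(self):
        utrs = [ul.UtrRecord("a", "three_prime", "A" * 100),
                ul.UtrRecord("b", "three_prime", "A" * 200)]
        s = ul.utr_stats(utrs)
        assert s["mean_utr3_length"] == 150.0
        assert s["n_utr3"] == 2 and s["n_utr5"] == 0

    def test_corpus_matches_manifest(self, corpus7):
        utrs = ul.extract_utrs(corpus7.models, corpus7.contigs)
        s = ul.utr_stats(utrs)
        t = corpus7.manifest["metrics"]
        assert s["n_utr3"] == t["n_genes_with_utr3"]
        assert s["n_utr5"] == t["n_genes_with_utr5"]
        assert s["mean_utr3_length"] == pytest.approx(t["mean_utr3_length"])
        assert s["mean_utr5_length"] == pytest.approx(t["mean_utr5_length"])
        assert s["n_introns_in_utr5"] == t["n_introns_in_utr5"]
        assert s["n_introns_in_utr3"] == t["n_introns_in_utr3"]
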