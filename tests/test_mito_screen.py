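"""Mitochondrial-hallmark screen: RBH, targeting consensus, tail anchor,
beta-signal/MBOMP filters, HMM join and aggregation."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mxpipe import mito_screen as ms
from mxpipe.io_core import HitRecord, PipelineConfig, ValidationError
from mxpipe.synthetic_data import HYDROPHOBIC, POLAR, _AA20


def _hit(q, s, e, bits=100.0):
    return HitRecord(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


def rbh_oracle(fwd, rev, emax=0.001):
    """Brute force: best = min over (evalue, -bitscore, subject)."""
    def best(hits):
        out = {}
        for h in hits:
            if h.evalue > emax:
                continue
            key = (h.evalue, -h.bitscore, h.subject)
            if h.query not in out or key < out[h.query][0]:
                out[h.query] = (key, h.subject)
        return {q: s for q, (_, s) in out.items()}
    fb, rb = best(fwd), best(rev)
    return sorted(
        (q, s) for q, s in fb.items() if rb.get(s) == q
    )


class TestRBH:
    def test_empty_tables(self):
        assert ms.reciprocal_best_hits([], []) == []

    def test_mutual_pair_found_one_way_excluded(self):
        fwd = [_hit("p1", "d1", 1e-10), _hit("p2", "d1", 1e-8)]
        rev = [_hit("d1", "p1", 1e-10)]
        assert ms.reciprocal_best_hits(fwd, rev) == [("p1", "d1")]

    def test_evalue_threshold_boundary(self):
        fwd = [_hit("p1", "d1", 0.01)]
        rev = [_hit("d1", "p1", 0.01)]
        assert ms.reciprocal_best_hits(fwd, rev) == []
        fwd = [_hit("p1", "d1", 0.001)]
        rev = [_hit("d1", "p1", 0.001)]
        assert ms.reciprocal_best_hits(fwd, rev) == [("p1", "d1")]

    def test_symmetry_under_table_swap(self):
        rng = np.random.default_rng(0)
        fwd, rev = self._random_tables(rng)
        pairs = set(ms.reciprocal_best_hits(fwd, rev))
        swapped = {(s, q) for q, s in ms.reciprocal_best_hits(rev, fwd)}
        assert pairs == swapped

    @staticmethod
    def _random_tables(rng, nq=30, ns=30, n=120):
        fwd = [
            _hit(f"p{rng.integers(nq)}", f"d{rng.integers(ns)}",
                 10.0 ** rng.uniform(-12, 1), float(rng.uniform(30, 200)))
            for _ in range(n)
        ]
        rev = [
            _hit(f"d{rng.integers(ns)}", f"p{rng.integers(nq)}",
                 10.0 ** rng.uniform(-12, 1), float(rng.uniform(30, 200)))
            for _ in range(n)
        ]
        return fwd, rev

    def test_matches_bruteforce_oracle_on_random_tables(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fwd, rev = self._random_tables(rng)
            assert ms.reciprocal_best_hits(fwd, rev) == rbh_oracle(fwd, rev)

    def test_corpus_recovers_planted_pairs(self, corpus7):
        p = corpus7.proteome
        got = ms.reciprocal_best_hits(p.hits_fwd, p.hits_rev)
        assert got == sorted(tuple(x) for x in p.manifest["rbh_pairs"])


class TestTargetingConsensus:
    def test_and_logic_and_strictness(self):
        a = {"p1": 0.6, "p2": 0.51, "p3": 0.5}
        b = {"p1": 0.4, "p2": 0.51, "p3": 0.9}
        flagged, _ = ms.targeting_consensus(a, b)
        assert flagged == {"p2"}  # 0.6/0.4 fails AND; 0.5 fails strict >

    def test_rate_percentage(self):
        a = {f"p{i}": 0.9 for i in range(24)}
        ids = [f"p{i}" for i in range(4665)]
        flagged, rate = ms.targeting_consensus(a, dict(a), proteome=ids)
        assert len(flagged) == 24 and rate == 0.5

    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError):
            ms.targeting_consensus({"p": 1.2}, {"p": 0.4})

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        a = {f"p{i}": float(rng.random()) for i in range(200)}
        b = {f"p{i}": float(rng.random()) for i in range(200)}
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            cur, _ = ms.targeting_consensus(a, b, thr)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_corpus_recovers_planted_positives(self, corpus7):
        p = corpus7.proteome
        flagged, rate = ms.targeting_consensus(
            ms.scores_to_map(p.scores, "targetp"),
            ms.scores_to_map(p.scores, "mitofates"),
            proteome=[r.id for r in p.proteins],
        )
        assert flagged == set(p.manifest["targeting"])
        assert rate == 0.5


class TestTailAnchor:
    @pytest.mark.parametrize("end,included", [
        (90, True),    # distance 10
        (50, False),   # distance 50
        (68, True),    # distance exactly 32 (inclusive)
        (67, False),   # distance 33
    ])
    def test_distance_rule(self, end, included):
        got = ms.tail_anchor_filter(
            {"p": 100}, [ms.TmdInterval("p", end - 19, end)])
        assert (got == {"p"}) is included

    def test_out_of_bounds_tmd_rejected(self):
        with pytest.raises(ValidationError):
            ms.tail_anchor_filter({"p": 50}, [ms.TmdInterval("p", 40, 60)])

    def test_corpus_recovery(self, corpus7):
        p = corpus7.proteome
        lengths = {r.id: len(r.seq) for r in p.proteins}
        tmds = [ms.TmdInterval(r.protein_id, int(r.start), int(r.end),
                               str(r.source))
                for r in p.tmd.itertuples(index=False)]
        assert ms.tail_anchor_filter(lengths, tmds) == set(p.manifest["ta"])


class TestHydropathyFallback:
    def test_hydrophobic_run_found(self):
        seq = "D" * 30 + "L" * 30 + "D" * 30
        (tmd,) = ms.hydropathy_tmd_fallback(seq)
        assert tmd.source == "hydropathy_fallback"
        assert 25 <= tmd.start <= 40 and 50 <= tmd.end <= 65

    def test_all_polar_empty(self):
        assert ms.hydropathy_tmd_fallback("D" * 80) == []

    def test_infinite_threshold_empty(self):
        assert ms.hydropathy_tmd_fallback("L" * 80,
                                          threshold=float("inf")) == []


_BETA_RE = re.compile(
    f"(?=([{POLAR}].G[{HYDROPHOBIC}].[{HYDROPHOBIC}].[{HYDROPHOBIC}]))"
)


def beta_oracle(seq, window=15):
    """Regex-based overlapping scan restricted to the C-terminal window."""
    n = len(seq)
    return [
        m.start() + 1 for m in _BETA_RE.finditer(seq)
        if n - (m.start() + 8) <= window
    ]


class TestBetaSignal:
    def test_constructed_terminal_motif(self):
        # S(Po) A(x) G L(Hy) A(x) L(Hy) I(x) L(Hy)
        seq = "M" * 50 + "SAGLALIL"
        hits = ms.beta_signal_scan(seq)
        assert [h.start for h in hits] == [51]
        assert hits[0].primary

    def test_motif_outside_window_ignored(self):
        seq = "M" * 20 + "SAGLALIL" + "D" * 40
        assert ms.beta_signal_scan(seq) == []

    @settings(max_examples=1000, derandomize=True)
    @given(st.text(alphabet=_AA20, min_size=8, max_size=200))
    def test_matches_regex_oracle(self, seq):
        got = [h.start for h in ms.beta_signal_scan(seq)]
        assert got == beta_oracle(seq)


class TestMbompFilter:
    def _protein(self, ctx_ss):
        n = len(ctx_ss) + 8
        seq = "A" * (n - 8) + "SAGLALIL"
        return seq, ctx_ss

    def test_strand_rich_context_passes(self):
        ctx = "E" * 80 + "H" * 20 + "C" * 200
        seq, _ = self._protein(ctx)
        hit = ms.beta_signal_scan(seq)[0]
        res = ms.mbomp_filter(seq, hit, ctx + "CCCCEEEE")
        assert res.passed
        assert res.strand_fraction == pytest.approx(80 / 300)

    def test_exact_threshold_boundaries_pass(self):
        ctx = "E" * 75 + "H" * 30 + "C" * 195     # exactly 25 % E, 10 % H
        seq, _ = self._protein(ctx)
        hit = ms.beta_signal_scan(seq)[0]
        res = ms.mbomp_filter(seq, hit, ctx + "HHHHEEEE")  # exactly 50 % H
        assert res.passed

    def test_one_residue_beyond_each_threshold_fails(self):
        seq = "A" * 300 + "SAGLALIL"
        hit = ms.beta_signal_scan(seq)[0]
        low_e = "E" * 74 + "C" * 226
        assert not ms.mbomp_filter(seq, hit, low_e + "CCCCEEEE").passed
        high_h = "E" * 80 + "H" * 31 + "C" * 189
        assert not ms.mbomp_filter(seq, hit, high_h + "CCCCEEEE").passed
        good = "E" * 80 + "H" * 20 + "C" * 200
        assert not ms.mbomp_filter(seq, hit, good + "HHHHHCCC").passed

    def test_ss_length_mismatch_rejected(self):
        seq = "A" * 300 + "SAGLALIL"
        hit = ms.beta_signal_scan(seq)[0]
        with pytest.raises(ValidationError):
            ms.mbomp_filter(seq, hit, "C" * 100)

    def test_corpus_screen_finds_exactly_planted(self, corpus7):
        p = corpus7.proteome
        got = ms.mbomp_screen(p.proteins, p.ss3)
        assert got == set(p.manifest["mbomp"])


class TestHmmJoin:
    def test_empty(self):
        out = ms.hmm_candidate_join(
            pd.DataFrame(columns=["protein", "profile", "evalue"]),
            pd.DataFrame(columns=["protein", "db_subject", "evalue"]))
        assert out.empty

    def test_mirrored_28_of_6_fixture(self):
        hmm = pd.DataFrame(
            [(f"p{i}", "PF1", 1e-9) for i in range(28)],
            columns=["protein", "profile", "evalue"])
        db = pd.DataFrame(
            [(f"p{i}", "mm", 1e-6) for i in range(6)],
            columns=["protein", "db_subject", "evalue"])
        out = ms.hmm_candidate_join(hmm, db)
        assert len(out) == 28
        assert int(out["has_db_homolog"].sum()) == 6

    def test_duplicates_deduplicated(self):
        hmm = pd.DataFrame(
            [("p1", "PF1", 1e-9), ("p1", "PF1", 1e-9)],
            columns=["protein", "profile", "evalue"])
        out = ms.hmm_candidate_join(hmm, None)
        assert len(out) == 1 and out.loc[0, "n_profiles"] == 1


class TestAggregate:
    def test_no_flags_all_rejected(self):
        df, summary = ms.aggregate_report(["p1", "p2"])
        assert (df["verdict"] == "rejected").all()
        assert summary["union"] == 0

    def test_all_channels_single_protein(self):
        df, summary = ms.aggregate_report(
            ["p1"], [("p1", "d1")], ["p1"], ["p1"], ["p1"], ["p1"])
        assert summary["union"] == 1
        row = df.iloc[0]
        assert row[["rbh", "hmm_hit", "targeting_consensus", "tail_anchor",
                    "mbomp"]].all()
        assert row["verdict"] == "manual_review"

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValidationError):
            ms.aggregate_report(["p1"], targeting_ids=["ghost"])

    def test_corpus_channel_counts_match_manifest(self, corpus7):
        p = corpus7.proteome
        ids = [r.id for r in p.proteins]
        flagged, _ = ms.targeting_consensus(
            ms.scores_to_map(p.scores, "targetp"),
            ms.scores_to_map(p.scores, "mitofates"), proteome=ids)
        lengths = {r.id: len(r.seq) for r in p.proteins}
        tmds = [ms.TmdInterval(r.protein_id, int(r.start), int(r.end))
                for r in p.tmd.itertuples(index=False)]
        ta = ms.tail_anchor_filter(lengths, tmds)
        mbomp = ms.mbomp_screen(p.proteins, p.ss3)
        pairs = ms.reciprocal_best_hits(p.hits_fwd, p.hits_rev)
        hmm = ms.hmm_candidate_join(p.hmm_hits, p.db_hits)
        df, summary = ms.aggregate_report(
            ids, pairs, list(hmm["protein"]), flagged, ta, mbomp)
        man = p.manifest
        assert summary["n_targeting_consensus"] == len(man["targeting"])
        assert summary["n_tail_anchor"] == len(man["ta"])
        assert summary["n_mbomp"] == len(man["mbomp"])
        assert summary["n_rbh"] == len(man["rbh_pairs"])
        assert summary["n_hmm_hit"] == len(man["hmm"])
        assert (df["verdict"] == "manual_review").sum() == summary["union"]
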