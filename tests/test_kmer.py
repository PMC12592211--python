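"""YGS k-mer statistic: hand examples, brute-force oracle equivalence,
monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvsdr import kmer
from uvsdr.core_io import SequenceSet, WindowSpec, make_windows
from uvsdr.kmer import KmerConfig, KmerSet


# --- independent brute-force oracle (string-based, no packing) -------------

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_count_kmers(seqs, k, canonical=True, min_count=1):
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            sub = seq[i:i + k]
            if set(sub) - set("ACGT"):
                continue
            if canonical:
                sub = min(sub, _rc(sub))
            counts[sub] = counts.get(sub, 0) + 1
    return {s: c for s, c in counts.items() if c >= min_count}


def brute_single_copy(records, k):
    counts = brute_count_kmers(records.values(), k)
    out = {}
    for chrom, seq in records.items():
        for i in range(len(seq) - k + 1):
            sub = seq[i:i + k]
            if set(sub) - set("ACGT"):
                continue
            if counts.get(min(sub, _rc(sub))) == 1:
                out.setdefault(chrom, []).append((i, min(sub, _rc(sub))))
    return out


# ---------------------------------------------------------------------------

class TestCountReadKmers:
    def test_hand_enumeration_with_reverse_complements(self):
        # ACGTA: ACG, CGT, GTA -> canonical ACG (CGT rc of ACG), GTA < TAC
        ks = kmer.count_read_kmers(["ACGTA"], KmerConfig(k=3, min_count=1))
        assert ks.to_dict() == {"ACG": 2, "GTA": 1}

    def test_min_count_drops_rare_kmers(self):
        reads = ["AAAC"] * 4  # AAA x4, AAC x4
        ks = kmer.count_read_kmers(reads, KmerConfig(k=3, min_count=5))
        assert len(ks) == 0
        ks = kmer.count_read_kmers(reads * 2, KmerConfig(k=3, min_count=5))
        assert ks.to_dict() == {"AAA": 8, "AAC": 8}

    def test_empty_read_set(self):
        ks = kmer.count_read_kmers([], KmerConfig(k=3, min_count=1))
        assert len(ks) == 0

    def test_k_longer_than_reads_warns_and_empties(self, caplog):
        ks = kmer.count_read_kmers(["ACGT"], KmerConfig(k=15, min_count=1))
        assert len(ks) == 0

    def test_n_bases_skipped(self):
        ks = kmer.count_read_kmers(["AANAA"], KmerConfig(k=3, min_count=1))
        assert ks.to_dict() == {}

    def test_low_quality_bases_skipped(self):
        from uvsdr.reads import ReadSet

        rs = ReadSet.from_sequences(["AAAAA"], quals=["II!II"])
        ks = kmer.count_read_kmers(rs, KmerConfig(k=3, min_count=1,
                                                  min_base_quality=20))
        assert len(ks) == 0  # every 3-mer spans the phred-0 base

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=5, max_size=40),
                    min_size=1, max_size=8),
           st.integers(2, 5))
    def test_matches_brute_force(self, seqs, k):
        seqs = [s for s in seqs if len(s) >= k]
        if not seqs:
            return
        lengths = {len(s) for s in seqs}
        # uniform length required by the matrix container; pad via grouping
        for L in lengths:
            group = [s for s in seqs if len(s) == L]
            ks = kmer.count_read_kmers(group, KmerConfig(k=k, min_count=1))
            assert ks.to_dict() == brute_count_kmers(group, k)


class TestSingleCopy:
    def test_homopolymer_has_no_single_copy(self):
        sc = kmer.genome_single_copy_kmers(SequenceSet({"c": "AAAA"}),
                                           KmerConfig(k=3))
        assert sc.total() == 0

    def test_forward_and_rc_collapse(self):
        # ACGTT: ACG/CGT canonical ACG twice; GTT -> AAC once
        sc = kmer.genome_single_copy_kmers(SequenceSet({"c": "ACGTT"}),
                                           KmerConfig(k=3))
        assert sc.as_set() == {"AAC"}

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_on_random_contigs(self, seed):
        rng = np.random.default_rng(seed)
        records = {
            f"c{i}": "".join(rng.choice(list("ACGT"), size=int(n)))
            for i, n in enumerate(rng.integers(50, 400, size=3))
        }
        sc = kmer.genome_single_copy_kmers(SequenceSet(records),
                                           KmerConfig(k=7))
        expected = brute_single_copy(records, 7)
        for chrom in records:
            got = list(zip(sc.positions.get(chrom, []),
                           sc.codes.get(chrom, [])))
            want = expected.get(chrom, [])
            assert [int(p) for p, _ in got] == [p for p, _ in want]

    def test_mostly_single_copy_on_random_kb_contigs(self):
        rng = np.random.default_rng(0)
        records = {f"c{i}": "".join(rng.choice(list("ACGT"), size=1000))
                   for i in range(3)}
        sc = kmer.genome_single_copy_kmers(SequenceSet(records),
                                           KmerConfig(k=15))
        n_kmers = sum(len(s) - 14 for s in records.values())
        assert sc.total() / n_kmers > 0.99  # collisions ~ n/4^15


class TestScoring:
    def _score(self, seq, opp_kmers, k=3, width=None):
        asm = SequenceSet({"c": seq})
        windows = make_windows(asm.lengths(), WindowSpec(width or len(seq)))
        cfg = KmerConfig(k=k, min_count=1)
        codes = [kmer._encode.encode_kmer(s) for s in opp_kmers]
        canon = [min(c, kmer._encode.revcomp_code(c, k)) for c in codes]
        opp = KmerSet(np.array(canon, dtype=np.uint64),
                      np.ones(len(canon), dtype=np.int64), k)
        return kmer.ygs_score_windows(asm, windows, opp, cfg)

    def test_all_matched_scores_zero(self):
        scores = self._score("ACGGT", ["ACG", "CGG", "GGT"])
        assert scores[0].pct_unmatched == 0.0

    def test_none_matched_scores_hundred(self):
        scores = self._score("ACGGT", [])
        assert scores[0].pct_unmatched == 100.0

    def test_half_matched_scores_fifty(self):
        # single-copy 3-mers of ACGGT: ACG, CGG, GGT (all unique)
        scores = self._score("ACGGT", ["ACG", "CGG"])
        assert scores[0].n_single_copy == 3
        sc = self._score("ACGGA", ["ACG"])  # ACG, CGG, GGA
        half = self._score("ACGG", ["ACG"])  # ACG, CGG -> 1 of 2 matched
        assert half[0].pct_unmatched == 50.0

    def test_unknown_chromosome_rejected(self):
        from uvsdr.core_io import Window

        asm = SequenceSet({"c": "ACGT"})
        opp = kmer.count_read_kmers([], KmerConfig(k=3, min_count=1))
        with pytest.raises(ValueError, match="unknown sequence"):
            kmer.ygs_score_windows(asm, [Window("zzz", 0, 4)], opp,
                                   KmerConfig(k=3, min_count=1))

    def test_mismatched_kmerset_config_rejected(self):
        asm = SequenceSet({"c": "ACGTACGT"})
        windows = make_windows(asm.lengths(), WindowSpec(8))
        opp = kmer.count_read_kmers([], KmerConfig(k=5, min_count=1))
        with pytest.raises(ValueError, match="mismatch"):
            kmer.ygs_score_windows(asm, windows, opp, KmerConfig(k=3))

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_under_opp_shrinkage(self, seed):
        """Removing k-mers from the opposite-sex set never lowers any
        window's unmatched percentage."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        asm = SequenceSet({"c": seq})
        windows = make_windows(asm.lengths(), WindowSpec(100))
        cfg = KmerConfig(k=5, min_count=1)
        reads = ["".join(rng.choice(list("ACGT"), size=30))
                 for _ in range(20)] + [seq[:30], seq[100:130]]
        full = kmer.count_read_kmers(reads, cfg)
        keep = rng.random(len(full)) < 0.5
        reduced = KmerSet(full.codes[keep], full.counts[keep], cfg.k)
        s_full = kmer.ygs_score_windows(asm, windows, full, cfg)
        s_red = kmer.ygs_score_windows(asm, windows, reduced, cfg)
        for a, b in zip(s_full, s_red):
            assert b.pct_unmatched >= a.pct_unmatched


class TestCalling:
    def _scores(self, pcts, chrom="c", width=10):
        out = []
        for i, pct in enumerate(pcts):
            from uvsdr.core_io import Window

            w = Window(chrom, i * width, (i + 1) * width)
            if pct is None:
                out.append(kmer.WindowKmerScore(w, 0, 0))
            else:
                out.append(kmer.WindowKmerScore(w, 1000, int(10 * pct)))
        return out

    def test_threshold_is_inclusive(self):
        calls = kmer.call_candidate_windows(self._scores([50.0]))
        assert len(calls) == 1

    def test_just_below_threshold_not_retained(self):
        assert kmer.call_candidate_windows(self._scores([49.9])) == []

    def test_adjacent_windows_merge(self):
        calls = kmer.call_candidate_windows(
            self._scores([10, 80, 80, 80, 10]))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (10, 40)

    def test_na_windows_never_retained(self):
        calls = kmer.call_candidate_windows(self._scores([None, 90]))
        assert len(calls) == 1 and calls[0].start == 10


def test_scan_equals_brute_force_end_to_end():
    """Full scan against a direct substring-enumeration oracle on a
    kilobase-scale assembly."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    asm = SequenceSet({"c": seq})
    cfg = KmerConfig(k=9, min_count=1)
    reads = [seq[i:i + 50] for i in range(0, 1800, 25)]
    opp = kmer.count_read_kmers(reads, cfg)
    windows = make_windows(asm.lengths(), WindowSpec(1000))
    scores = kmer.ygs_score_windows(asm, windows, opp, cfg)

    opp_brute = set(brute_count_kmers(reads, 9))
    single = brute_single_copy({"c": seq}, 9)["c"]
    for w, score in zip(windows, scores):
        mine = [(p, s) for p, s in single if w.start <= p < w.end]
        unmatched = [s for _, s in mine if s not in opp_brute]
        assert score.n_single_copy == len(mine)
        assert score.n_unmatched == len(unmatched)
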