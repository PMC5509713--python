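from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnckit.seqcore import (
    KmerModel,
    Transcript,
    find_orfs,
    kmer_coding_score,
    longest_orf_aa,
    read_fasta,
    reverse_complement,
    train_kmer_model,
)

STOPS = {"TAA", "TAG", "TGA"}

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def brute_longest_orf_aa(seq: str) -> int:
    """Exhaustive oracle: longest stop-free in-frame codon substring.

    Scans every substring of length divisible by 3 on both strands; a
    substring counts if none of its in-frame codons is a stop.
    """
    best = 0
    for s in (seq, reverse_complement(seq)):
        n = len(s)
        for i in range(n):
            for j in range(i + 3, n + 1, 3):
                codons = [s[k : k + 3] for k in range(i, j, 3)]
                if any(c in STOPS for c in codons):
                    continue
                best = max(best, (j - i) // 3)
    return best


class TestReadFasta:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_case_and_u_normalization(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">t1\nacgu\n")
        (t,) = read_fasta(path)
        assert t.id == "t1" and t.sequence == "ACGT" and t.length == 4

    def test_duplicate_id_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(path)

    def test_empty_record_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\n\n>b\nACGT\n")
        with pytest.raises(ValueError, match="empty sequence"):
            read_fasta(path)

    def test_non_iupac_error_reports_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACXGT\n")
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(path)


class TestFindOrfs:
    def test_no_stops_whole_frame(self):
        t = Transcript("t", "AAAAAAAAA")
        orfs = find_orfs(t, "+")
        frame0 = [o for o in orfs if o.frame == 0]
        assert len(frame0) == 1
        assert frame0[0].aa_length == 3 and frame0[0].peptide == "KKK"
        assert {o.aa_length for o in orfs if o.frame in (1, 2)} == {2}

    def test_stop_to_stop_example(self):
        t = Transcript("t", "TAAATGAAACCCTGA")
        orfs = [o for o in find_orfs(t, "+") if o.frame == 0 and o.peptide]
        assert any(o.peptide == "MKP" and o.aa_length == 3 and (o.start, o.end) == (3, 12)
                   for o in orfs)

    def test_short_sequence_empty(self):
        assert find_orfs(Transcript("t", "AA"), "+") == []

    def test_no_start_codon_required(self):
        # stop-to-stop: a run with no ATG still counts
        t = Transcript("t", "TAACCCCCCTAA")
        orfs = [o for o in find_orfs(t, "+") if o.frame == 0]
        assert [o.peptide for o in orfs] == ["PP"]

    def test_strand_union_decomposition(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        for _ in range(20):
            seq = "".join(rng.choice(list(bases), size=rng.integers(3, 50)))
            t = Transcript("t", seq)
            both = {(o.strand, o.frame, o.start, o.end) for o in find_orfs(t, "+-")}
            split = {(o.strand, o.frame, o.start, o.end) for o in find_orfs(t, "+")} | {
                (o.strand, o.frame, o.start, o.end) for o in find_orfs(t, "-")
            }
            assert both == split

    def test_invalid_strands(self):
        with pytest.raises(ValueError):
            find_orfs(Transcript("t", "ACGTACGT"), strands=())
        with pytest.raises(ValueError):
            find_orfs(Transcript("t", "ACGTACGT"), strands=("x",))

    @given(dna)
    @settings(max_examples=60, deadline=None)
    def test_interval_invariants(self, seq):
        t = Transcript("t", seq)
        orfs = find_orfs(t)
        by_strand_frame: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for o in orfs:
            assert 0 <= o.start < o.end <= t.length
            assert (o.end - o.start) % 3 == 0
            assert "*" not in o.peptide
            by_strand_frame.setdefault((o.strand, o.frame), []).append((o.start, o.end))
        for intervals in by_strand_frame.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2


class TestLongestOrf:
    def test_worked_example(self):
        # frame 0 holds MKP (3 aa) but frame 2 has the stop-free run
        # AAT GAA ACC CTG (4 aa); the brute-force oracle agrees on 4
        seq = "TAAATGAAACCCTGA"
        assert brute_longest_orf_aa(seq[:]) >= 4
        assert longest_orf_aa(Transcript("t", seq), "+") == 4

    def test_too_short(self):
        assert longest_orf_aa(Transcript("t", "AA")) == 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 61)))
            t = Transcript("t", seq)
            assert longest_orf_aa(t) == brute_longest_orf_aa(seq), seq

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            fwd = longest_orf_aa(Transcript("t", seq))
            rev = longest_orf_aa(Transcript("t", reverse_complement(seq)))
            assert fwd == rev

    def test_n_codons_are_not_stops(self):
        # TAN could be TAA/TAG but is translated as X, never a stop
        t = Transcript("t", "ATGTANAAA")
        orfs = [o for o in find_orfs(t, "+") if o.frame == 0]
        assert orfs[0].aa_length == 3 and orfs[0].peptide == "MXK"


class TestKmerModel:
    def _toy(self):
        coding = [Transcript("c", "A" * 40)]
        noncoding = [Transcript("n", "C" * 40)]
        return train_kmer_model(coding, noncoding, k_max=2, pseudocount=0.5)

    def test_identical_sets_zero_logodds(self):
        ts = [Transcript("a", "ACGTACGTAC")]
        model = train_kmer_model(ts, ts, k_max=3, pseudocount=1.0)
        assert all(v == pytest.approx(0.0) for v in model.log_odds.values())

    def test_signs_forced(self):
        model = self._toy()
        assert model.log_odds["A"] > 0 and model.log_odds["C"] < 0

    def test_determinism(self):
        coding = [Transcript("c", "ACGTACGTAGGT")]
        noncoding = [Transcript("n", "TTTTAAGGCCTT")]
        m1 = train_kmer_model(coding, noncoding)
        m2 = train_kmer_model(coding, noncoding)
        assert m1.log_odds == m2.log_odds

    def test_invalid_params(self):
        ts = [Transcript("a", "ACGT")]
        with pytest.raises(ValueError):
            train_kmer_model(ts, ts, k_max=0)
        with pytest.raises(ValueError):
            train_kmer_model(ts, ts, pseudocount=0.0)
        with pytest.raises(ValueError):
            train_kmer_model([], ts)

    def test_score_hand_summation(self):
        model = KmerModel(k_max=1, pseudocount=1.0,
                          log_odds={"A": 4.0, "C": 0.0, "G": 0.0, "T": 0.0})
        assert kmer_coding_score(Transcript("t", "ACGT"), model) == pytest.approx(1.0)

    def test_all_zero_model(self):
        model = KmerModel(k_max=2, pseudocount=1.0,
                          log_odds={w: 0.0 for w in
                                    [a + b for a in "ACGT" for b in "ACGT"] + list("ACGT")})
        assert kmer_coding_score(Transcript("t", "ACGTACGT"), model) == 0.0

    def test_training_class_separation(self):
        model = self._toy()
        a = kmer_coding_score(Transcript("x", "A" * 20), model)
        c = kmer_coding_score(Transcript("y", "C" * 20), model)
        assert a > 0 > c

    def test_score_id_invariant(self):
        model = self._toy()
        s1 = kmer_coding_score(Transcript("one", "AACC"), model)
        s2 = kmer_coding_score(Transcript("two", "AACC"), model)
        assert s1 == s2

    def test_save_load_roundtrip(self, tmp_path):
        model = self._toy()
        path = tmp_path / "model.tsv"
        model.save(path)
        loaded = KmerModel.load(path)
        assert loaded.k_max == model.k_max
        assert loaded.pseudocount == model.pseudocount
        assert loaded.log_odds == model.log_odds

    def test_n_kmers_skipped(self):
        model = KmerModel(k_max=1, pseudocount=1.0,
                          log_odds={"A": 2.0, "C": 0.0, "G": 0.0, "T": 0.0})
        # N positions contribute nothing
        assert kmer_coding_score(Transcript("t", "ANAN"), model) == pytest.approx(2.0)
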