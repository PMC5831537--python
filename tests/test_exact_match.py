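"""Seed-and-merge longest exact match vs a brute-force LCS oracle."""

import numpy as np
import pytest

from conftest import lcs_length_both_strands, naive_revcomp, random_seq
from phagehost.exact_match import (
    build_seed_index,
    exact_match_scores,
    longest_exact_match,
    match_length_histogram,
)
from phagehost.sequence import SequenceRecord


class TestSeedIndex:
    def test_poly_a_host_has_16_seed_positions(self):
        idx = build_seed_index([SequenceRecord("h", "A" * 30)])
        assert len(idx.seed_positions("h", "A" * 15)) == 16  # 30 - 15 + 1

    def test_absent_seed_empty_lookup(self):
        idx = build_seed_index([SequenceRecord("h", "A" * 30)])
        assert len(idx.seed_positions("h", "C" * 15)) == 0

    def test_lookup_agrees_with_naive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            host = random_seq(rng, 600)
            idx = build_seed_index([SequenceRecord("h", host)])
            start = int(rng.integers(0, 600 - 15))
            word = host[start : start + 15]
            naive = [i for i in range(len(host) - 14) if host[i : i + 15] == word]
            assert list(idx.seed_positions("h", word)) == naive

    def test_seed_len_floor(self):
        with pytest.raises(ValueError):
            build_seed_index([], seed_len=7)

    def test_seeds_in_n_windows_never_indexed(self):
        idx = build_seed_index([SequenceRecord("h", "A" * 7 + "N" + "A" * 7 + "C" * 20)])
        assert len(idx.seed_positions("h", "A" * 15)) == 0


class TestLongestMatch:
    def test_full_phage_in_host(self):
        rng = np.random.default_rng(2)
        phage = SequenceRecord("p", random_seq(rng, 5000))
        host = SequenceRecord("h", random_seq(rng, 2000) + phage.seq + random_seq(rng, 2000))
        m = longest_exact_match(phage, host, build_seed_index([host]))
        assert m.length >= 5000  # chance boundary extension may add a base
        assert host.seq[m.host_pos : m.host_pos + m.length].find(phage.seq) != -1 or m.length == 5000

    def test_planted_20bp_island(self):
        rng = np.random.default_rng(3)
        island = random_seq(rng, 20)
        # embed in otherwise unrelated sequence; verify against the oracle
        phage = SequenceRecord("p", random_seq(rng, 1000) + island + random_seq(rng, 1000))
        host = SequenceRecord("h", random_seq(rng, 1500) + island + random_seq(rng, 1500))
        m = longest_exact_match(phage, host, build_seed_index([host]))
        assert m.length == lcs_length_both_strands(phage.seq, host.seq)

    def test_14bp_island_below_seed_length_is_invisible(self):
        rng = np.random.default_rng(4)
        island = random_seq(rng, 14)
        phage = SequenceRecord("p", random_seq(rng, 400) + island + random_seq(rng, 400))
        host = SequenceRecord("h", random_seq(rng, 400) + island + random_seq(rng, 400))
        m = longest_exact_match(phage, host, build_seed_index([host]))
        if lcs_length_both_strands(phage.seq, host.seq) < 15:
            assert m is None

    def test_oracle_equivalence_50_instances(self):
        """Reported length equals the brute-force LCS (both strands)
        whenever the LCS reaches the seed length; no match otherwise."""
        rng = np.random.default_rng(5)
        sizes = [(300, 500)] * 20 + [(800, 1500)] * 20 + [(2000, 5000)] * 10
        for t, (np_, nh) in enumerate(sizes):
            frag = random_seq(rng, int(rng.integers(8, 45)))
            p = random_seq(rng, np_)
            h = random_seq(rng, nh)
            cut_p = int(rng.integers(0, np_ - len(frag)))
            cut_h = int(rng.integers(0, nh - len(frag)))
            planted = frag if t % 2 else naive_revcomp(frag)
            p = p[:cut_p] + frag + p[cut_p + len(frag):]
            h = h[:cut_h] + planted + h[cut_h + len(frag):]
            phage, host = SequenceRecord("p", p), SequenceRecord("h", h)
            true_lcs = lcs_length_both_strands(p, h)
            m = longest_exact_match(phage, host, build_seed_index([host]))
            if true_lcs >= 15:
                assert m is not None and m.length == true_lcs
            else:
                assert m is None

    def test_reported_substrings_are_identical(self):
        rng = np.random.default_rng(6)
        island = random_seq(rng, 60)
        phage = SequenceRecord("p", random_seq(rng, 500) + island + random_seq(rng, 500))
        host = SequenceRecord(
            "h", random_seq(rng, 700) + naive_revcomp(island) + random_seq(rng, 700)
        )
        m = longest_exact_match(phage, host, build_seed_index([host]))
        sub_p = phage.seq[m.phage_pos : m.phage_pos + m.length]
        sub_h = host.seq[m.host_pos : m.host_pos + m.length]
        assert sub_p == (sub_h if m.strand == 1 else naive_revcomp(sub_h))

    def test_forward_only_flag_ignores_reverse_matches(self):
        rng = np.random.default_rng(7)
        island = random_seq(rng, 40)
        phage = SequenceRecord("p", random_seq(rng, 300) + island + random_seq(rng, 300))
        host = SequenceRecord("h", random_seq(rng, 300) + naive_revcomp(island) + random_seq(rng, 300))
        idx = build_seed_index([host])
        assert longest_exact_match(phage, host, idx, both_strands=True).length >= 40
        fwd = longest_exact_match(phage, host, idx, both_strands=False)
        assert fwd is None or fwd.length < 40


class TestScores:
    def test_containing_host_attains_row_maximum(self):
        rng = np.random.default_rng(8)
        phage = SequenceRecord("p", random_seq(rng, 2000))
        donor = SequenceRecord("d", random_seq(rng, 1000) + phage.seq + random_seq(rng, 1000))
        other = SequenceRecord("o", random_seq(rng, 4000))
        table = exact_match_scores([phage], [donor, other])
        assert "d" in table.top_hosts("p")
        assert table.scores.loc["p", "d"] >= 2000

    def test_unrelated_random_pairs_overwhelmingly_score_zero(self):
        """At sizes where a shared 15-mer is improbable, almost all pairs
        score 0 (none when no 15-mer is shared at all)."""
        rng = np.random.default_rng(9)
        phages = [SequenceRecord(f"p{i}", random_seq(rng, 2000)) for i in range(5)]
        hosts = [SequenceRecord(f"h{i}", random_seq(rng, 10000)) for i in range(4)]
        table = exact_match_scores(phages, hosts)
        # E[shared 15-mers] ~ 2*2e3*1e4/4^15 ~ 0.04 per pair
        frac_zero = (table.scores.to_numpy() == 0).mean()
        assert frac_zero >= 0.8

    def test_content_symmetry(self):
        rng = np.random.default_rng(10)
        a = SequenceRecord("a", random_seq(rng, 900))
        b_seq = a.seq[200:500] + random_seq(rng, 600)
        b = SequenceRecord("b", b_seq)
        m_ab = longest_exact_match(a, b, build_seed_index([b]))
        m_ba = longest_exact_match(b, a, build_seed_index([a]))
        assert m_ab.length == m_ba.length

    def test_monotonicity_longer_plant_never_scores_less(self):
        rng = np.random.default_rng(11)
        base_p = random_seq(rng, 1500)
        base_h = random_seq(rng, 3000)
        prev = 0
        for seg_len in (20, 60, 200, 600):
            p = base_p[:seg_len] + base_p[seg_len:]
            h = base_h[:1000] + base_p[:seg_len] + base_h[1000 + seg_len:]
            m = longest_exact_match(
                SequenceRecord("p", p), SequenceRecord("h", h),
                build_seed_index([SequenceRecord("h", h)]),
            )
            length = 0 if m is None else m.length
            assert length >= prev
            prev = length

    def test_histogram_splits_correct_and_incorrect(self):
        rng = np.random.default_rng(12)
        phage = SequenceRecord("p", random_seq(rng, 1000))
        right = SequenceRecord("r", random_seq(rng, 500) + phage.seq[100:400] + random_seq(rng, 500))
        wrong = SequenceRecord("w", random_seq(rng, 1200))
        table = exact_match_scores([phage], [right, wrong])
        hist = match_length_histogram(table, {"p": "r"}, [0, 100, 1000])
        assert hist["correct"].sum() == 1
        assert hist["incorrect"].sum() == 0
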