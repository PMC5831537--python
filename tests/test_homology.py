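"""Nucleotide/translated homology scoring and the tabular-hits adapter."""

import numpy as np
import pytest

from conftest import random_seq
from phagehost.homology import (
    TabularFormatError,
    homology_scores,
    nucleotide_alignments,
    nucleotide_homology,
    read_tabular_hits,
    summaries_to_scoretable,
    translated_homology,
    write_tabular_hits,
)
from phagehost.sequence import SequenceRecord, orf_peptides
from phagehost.simulate import _random_gene


class TestNucleotide:
    def test_planted_300bp_gene_bounds(self):
        rng = np.random.default_rng(0)
        gene = random_seq(rng, 300)
        phage = SequenceRecord("p", random_seq(rng, 2000) + gene + random_seq(rng, 2000))
        host = SequenceRecord("h", random_seq(rng, 5000) + gene + random_seq(rng, 5000))
        s = nucleotide_homology(phage, host)
        assert 300 <= s.total_aligned_len < 400

    def test_unrelated_pair_scores_near_zero(self):
        rng = np.random.default_rng(1)
        s = nucleotide_homology(
            SequenceRecord("p", random_seq(rng, 30_000)),
            SequenceRecord("h", random_seq(rng, 30_000)),
        )
        assert s.total_aligned_len < 50

    def test_full_containment_covers_whole_phage(self):
        rng = np.random.default_rng(2)
        phage = SequenceRecord("p", random_seq(rng, 3000))
        host = SequenceRecord("h", random_seq(rng, 1000) + phage.seq + random_seq(rng, 1000))
        assert nucleotide_homology(phage, host).total_aligned_len == 3000

    def test_reverse_strand_gene_found(self):
        from conftest import naive_revcomp

        rng = np.random.default_rng(3)
        gene = random_seq(rng, 400)
        phage = SequenceRecord("p", random_seq(rng, 1500) + gene + random_seq(rng, 1500))
        host = SequenceRecord("h", random_seq(rng, 2000) + naive_revcomp(gene) + random_seq(rng, 2000))
        s = nucleotide_homology(phage, host)
        assert s.total_aligned_len >= 400

    @pytest.mark.parametrize("seed", range(5))
    def test_diverged_gene_always_detected(self, seed):
        """A gene copied with 10% divergence is always found at defaults."""
        rng = np.random.default_rng(200 + seed)
        gene = random_seq(rng, 600)
        mutated = list(gene)
        for i in range(len(mutated)):
            if rng.random() < 0.10:
                mutated[i] = "ACGT"[("ACGT".index(mutated[i]) + int(rng.integers(1, 4))) % 4]
        phage = SequenceRecord("p", random_seq(rng, 1000) + "".join(mutated) + random_seq(rng, 1000))
        host = SequenceRecord("h", random_seq(rng, 2000) + gene + random_seq(rng, 2000))
        assert nucleotide_homology(phage, host).total_aligned_len >= 300


class TestTranslated:
    def test_verbatim_host_protein_matches(self):
        rng = np.random.default_rng(4)
        gene = _random_gene(600, rng)
        host = SequenceRecord("h", random_seq(rng, 4000) + gene + random_seq(rng, 4000))
        phage = SequenceRecord("p", random_seq(rng, 2000) + gene + random_seq(rng, 2000))
        s = translated_homology(phage, orf_peptides(host, 60))
        assert s.n_matching_proteins >= 1

    def test_twenty_percent_aa_divergence_still_matches(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        codon = {
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
            "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        }
        pep = "M" + "".join(aa[i] for i in rng.integers(0, 20, 199))
        diverged = list(pep)
        for i in range(1, len(diverged)):
            if rng.random() < 0.2:
                diverged[i] = aa[int(rng.integers(0, 20))]
        host_gene = "".join(codon[c] for c in pep) + "TAA"
        phage_gene = "".join(codon[c] for c in diverged) + "TAA"
        host = SequenceRecord("h", random_seq(rng, 3000) + host_gene + random_seq(rng, 3000))
        phage = SequenceRecord("p", random_seq(rng, 1000) + phage_gene + random_seq(rng, 1000))
        assert translated_homology(phage, orf_peptides(host, 60)).n_matching_proteins >= 1

    @pytest.mark.parametrize("seed", range(3))
    def test_unrelated_proteomes_no_matches(self, seed):
        rng = np.random.default_rng(300 + seed)
        phage = SequenceRecord("p", random_seq(rng, 15_000))
        host = SequenceRecord("h", random_seq(rng, 40_000))
        prots = orf_peptides(host, 60)
        if prots:
            assert translated_homology(phage, prots).n_matching_proteins == 0

    def test_empty_protein_set_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            translated_homology(SequenceRecord("p", random_seq(rng, 1000)), [])


class TestOverlapCollapse:
    def test_union_invariant_under_split_rows(self, tmp_path):
        """Splitting one alignment into two overlapping reported rows
        leaves the collapsed total unchanged."""
        row = "p\th\t100.0\t{length}\t0\t0\t{qs}\t{qe}\t1\t100\t0.0\t50"
        whole = tmp_path / "whole.tsv"
        whole.write_text(row.format(length=151, qs=100, qe=250) + "\n")
        split = tmp_path / "split.tsv"
        split.write_text(
            row.format(length=101, qs=100, qe=200) + "\n"
            + row.format(length=101, qs=150, qe=250) + "\n"
        )
        (a,) = read_tabular_hits(whole)
        (b,) = read_tabular_hits(split)
        assert a.total_aligned_len == b.total_aligned_len == 151

    def test_merged_overlap_151_bases(self, tmp_path):
        # 1-based inclusive 100-200 and 150-250 -> union 100..250 = 151
        path = tmp_path / "hits.tsv"
        path.write_text(
            "p\th\t99.0\t101\t1\t0\t100\t200\t500\t600\t1e-30\t90\n"
            "p\th\t99.0\t101\t1\t0\t150\t250\t550\t650\t1e-30\t90\n"
        )
        (summary,) = read_tabular_hits(path)
        assert summary.total_aligned_len == 151

    def test_empty_file_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_tabular_hits(path) == []

    def test_column_count_error_carries_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("p\th\t100.0\t50\n")
        with pytest.raises(TabularFormatError, match="line 1"):
            read_tabular_hits(path)

    def test_internal_hits_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        gene = random_seq(rng, 500)
        phage = SequenceRecord("p", random_seq(rng, 1000) + gene + random_seq(rng, 1000))
        host = SequenceRecord("h", random_seq(rng, 1500) + gene + random_seq(rng, 1500))
        hits = nucleotide_alignments(phage, host)
        assert hits
        path = tmp_path / "hits.tsv"
        write_tabular_hits(phage, host, hits, path)
        (summary,) = read_tabular_hits(path)
        assert summary.total_aligned_len == nucleotide_homology(phage, host).total_aligned_len


class TestScoreTables:
    def test_planted_donor_top_ranked_both_modes(self):
        rng = np.random.default_rng(8)
        gene = _random_gene(600, rng)
        phage = SequenceRecord("p", random_seq(rng, 2000) + gene + random_seq(rng, 2000))
        donor = SequenceRecord("d", random_seq(rng, 4000) + gene + random_seq(rng, 4000))
        other = SequenceRecord("o", random_seq(rng, 8600))
        for mode in ("nucleotide", "translated"):
            table = homology_scores([phage], [donor, other], mode=mode)
            assert table.top_hosts("p") == {"d"}, mode

    def test_table_shape_and_orientation(self, tiny_bundle):
        table = homology_scores(tiny_bundle.phages[:2], tiny_bundle.hosts[:3])
        assert table.scores.shape == (2, 3)
        assert table.higher_is_better

    def test_pairs_without_hits_are_no_evidence(self):
        rng = np.random.default_rng(9)
        phage = SequenceRecord("p", random_seq(rng, 2000))
        host = SequenceRecord("h", random_seq(rng, 2000))
        table = homology_scores([phage], [host])
        assert np.isnan(table.scores.loc["p", "h"])
        assert table.top_hosts("p") == set()

    def test_summaries_to_scoretable(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\th1\t100.0\t200\t0\t0\t1\t200\t1\t200\t0.0\t400\n")
        table = summaries_to_scoretable(read_tabular_hits(path), phage_ids=["p1", "p2"], host_ids=["h1"])
        assert table.scores.loc["p1", "h1"] == 200
        assert np.isnan(table.scores.loc["p2", "h1"])
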