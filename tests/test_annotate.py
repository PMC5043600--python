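"""Mismatch classification, A-to-I retention, features, coding effects,
neighbor preferences, miRNA-target overlap."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from intervaltree import IntervalTree

from editome.annotate import (assign_feature, classify_mismatch,
                              coding_effect, mirna_target_overlap,
                              mismatch_spectrum, neighbor_preference,
                              retain_a2i, splice_positions_from_models)
from editome.io import (Transcript, read_bed_intervals, write_bed,
                        in_intervals)


@pytest.fixture
def alu():
    return {"c": IntervalTree.from_tuples([(101, 201)])}  # 1-based [101,200]


class TestClassifyMismatch:
    def test_inside_alu(self, alu):
        region, mtype, _ = classify_mismatch("c", 150, "A", "G", alu, set())
        assert (region, mtype) == ("Alu", "A-to-G")

    def test_outside_alu(self, alu):
        assert classify_mismatch("c", 300, "A", "G", alu, set())[0] == "non-Alu"

    def test_bed_conversion_boundaries(self, tmp_path):
        """A 1-based closed interval [101, 200] written as BED and read
        back contains exactly its boundary positions."""
        bed = tmp_path / "alu.bed"
        write_bed([("c", 101, 200)], bed)
        trees = read_bed_intervals(bed)
        assert in_intervals(trees, "c", 101)
        assert in_intervals(trees, "c", 200)
        assert not in_intervals(trees, "c", 100)
        assert not in_intervals(trees, "c", 201)

    def test_catalogue_membership_strand_aware(self, alu):
        cat = {("c", 150, "+")}
        assert classify_mismatch("c", 150, "A", "G", alu, cat)[2]
        assert not classify_mismatch("c", 151, "A", "G", alu, cat)[2]


class TestRetainA2I:
    def test_alu_a2g_retained(self):
        assert retain_a2i("Alu", "A", "G", in_catalogue=False)

    def test_non_alu_a2g_needs_catalogue(self):
        assert not retain_a2i("non-Alu", "A", "G", in_catalogue=False)
        assert retain_a2i("non-Alu", "A", "G", in_catalogue=True)

    def test_alu_c2t_excluded(self):
        assert not retain_a2i("Alu", "C", "T", in_catalogue=False)

    def test_t2c_transcript_sense_vs_strict(self):
        assert retain_a2i("Alu", "T", "C", False, gene_strand="-")
        assert not retain_a2i("Alu", "T", "C", False, gene_strand="+")
        assert not retain_a2i("Alu", "T", "C", False, gene_strand="-",
                              t2c_mode="strict")


class TestNeighborPreference:
    def fetcher(self, seq):
        return lambda chrom, s, e: seq[s - 1:e]

    def test_single_site_flanks(self):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [2], "ref": ["A"]})
        out = neighbor_preference(sites, self.fetcher("CAGT"), {"c": 4})
        assert out["g_minus1"] == 0.0 and out["g_plus1"] == 1.0

    def test_t2c_reverse_complement(self):
        # genomic C T G: on the editing (antisense) strand the -1
        # neighbor is comp(G)=C and the +1 neighbor is comp(C)=G
        sites = pd.DataFrame({"chrom": ["c"], "pos": [2], "ref": ["T"]})
        out = neighbor_preference(sites, self.fetcher("CTGA"), {"c": 4})
        assert out["g_plus1"] == 1.0
        assert out["c_minus1"] == 1.0

    def test_uniform_sequence_near_quarter(self):
        rng = np.random.default_rng(17)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        pos = rng.integers(2, len(seq), 2_000)
        sites = pd.DataFrame({"chrom": "c", "pos": pos, "ref": "A"})
        out = neighbor_preference(sites, self.fetcher(seq),
                                  {"c": len(seq)})
        sd3 = 3 * np.sqrt(0.25 * 0.75 / out["n_sites"])
        assert abs(out["g_plus1"] - 0.25) < sd3
        assert abs(out["g_minus1"] - 0.25) < sd3

    def test_all_edge_sites_error(self):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1], "ref": ["A"]})
        with pytest.raises(ValueError):
            neighbor_preference(sites, self.fetcher("ACGT"), {"c": 4})


class TestAssignFeature:
    TX_PLUS = Transcript("t1", "g1", "c", "+", "protein_coding",
                         exons=((100, 199), (300, 499), (600, 799)),
                         cds=((350, 499), (600, 649)))
    TX_NC = Transcript("t2", "g2", "c", "+", "ncRNA", exons=((150, 250),))
    TX_INTRON = Transcript("t3", "g3", "c", "-", "protein_coding",
                           exons=((320, 340), (380, 420)),
                           cds=((380, 400),))

    def test_utr3(self):
        f, gid, strand = assign_feature("c", 700, [self.TX_PLUS])
        assert f == "3UTR" and gid == "g1" and strand == "+"

    def test_utr5(self):
        assert assign_feature("c", 150, [self.TX_PLUS])[0] == "5UTR"

    def test_cds_precedence_over_intron(self):
        # in t1's CDS and in t3's intron: CDS wins
        f, gid, _ = assign_feature("c", 360,
                                   [self.TX_INTRON, self.TX_PLUS])
        assert f == "CDS" and gid == "g1"

    def test_ncrna_when_only_noncoding(self):
        assert assign_feature("c", 230, [self.TX_NC])[0] == "ncRNA"

    def test_intergenic(self):
        assert assign_feature("c", 5000, [self.TX_PLUS])[0] == "intergenic"

    def test_splice_positions(self):
        sp = splice_positions_from_models([self.TX_PLUS])
        assert set(sp["c"]) == {199, 300, 499, 600}


class TestCodingEffect:
    def make_tx(self, seq_cds, strand="+", start=101):
        end = start + len(seq_cds) - 1
        tx = Transcript("t", "g", "c", strand, "protein_coding",
                        exons=((start, end),), cds=((start, end),))
        genome = "N" * (start - 1) + seq_cds + "NNNN"
        return tx, (lambda chrom, s, e: genome[s - 1:e])

    def test_lysine_to_glutamate(self):
        tx, fetch = self.make_tx("AAGTTT")
        effect, change = coding_effect("c", 101, "A", "G", tx, fetch)
        assert effect == "nonsynonymous"
        assert change == "K1E"

    def test_synonymous_third_position(self):
        tx, fetch = self.make_tx("GCATTT")
        effect, _ = coding_effect("c", 103, "A", "G", tx, fetch)
        assert effect == "synonymous"

    def test_minus_strand_transcript_sense(self):
        # genomic CTT on '-' = transcript AAG (Lys); genomic T>C at the
        # last genomic base is transcript A>G at codon position 1 -> Glu
        tx, fetch = self.make_tx("AAACTT", strand="-")
        effect, change = coding_effect("c", 106, "T", "C", tx, fetch)
        assert effect == "nonsynonymous"
        assert change == "K1E"

    def test_round_trip_against_full_translation(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n_codons = int(rng.integers(2, 30))
            cds = "".join("ACGT"[i] for i in rng.integers(0, 4, 3 * n_codons))
            strand = "+" if rng.random() < 0.5 else "-"
            tx, fetch = self.make_tx(cds, strand=strand)
            offs = [i for i, b in enumerate(cds)
                    if (strand == "+" and b == "A")
                    or (strand == "-" and b == "T")]
            if not offs:
                continue
            off = offs[int(rng.integers(0, len(offs)))]
            alt = "G" if strand == "+" else "C"
            effect, _ = coding_effect("c", 101 + off, cds[off], alt, tx, fetch)
            edited = cds[:off] + alt + cds[off + 1:]
            if strand == "-":
                before = str(Seq(cds).reverse_complement().translate())
                after = str(Seq(edited).reverse_complement().translate())
            else:
                before = str(Seq(cds).translate())
                after = str(Seq(edited).translate())
            assert effect == ("synonymous" if before == after
                              else "nonsynonymous")

    def test_errors_outside_cds_and_bad_length(self):
        tx, fetch = self.make_tx("AAGTTT")
        with pytest.raises(ValueError):
            coding_effect("c", 99, "A", "G", tx, fetch)
        bad = Transcript("t", "g", "c", "+", "protein_coding",
                         exons=((101, 104),), cds=((101, 104),))
        with pytest.raises(ValueError):
            coding_effect("c", 101, "A", "G", bad, fetch)


class TestMirnaTarget:
    targets = {"c": IntervalTree.from_tuples([(500, 551)])}

    def test_utr3_site_in_interval(self):
        assert mirna_target_overlap("c", 520, "3UTR", self.targets)

    def test_cds_site_excluded(self):
        assert not mirna_target_overlap("c", 520, "CDS", self.targets)

    def test_outside_interval(self):
        assert not mirna_target_overlap("c", 600, "3UTR", self.targets)


def test_mismatch_spectrum_fractions_sum_to_one(small_result):
    spec = mismatch_spectrum(small_result.candidates.loc[
        small_result.candidates["detected"]])
    sums = spec.groupby("cell_id")["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0)


def test_alu_spectrum_dominated_by_a2g(small_result, small_cohort):
    """On ADAR-driven simulated data, A-to-G (plus antisense T-to-C)
    accounts for the overwhelming share of Alu-region detections."""
    det = small_result.annotated
    alu = det.loc[det["is_alu"]]
    a2g = ((alu["ref"] == "A") & (alu["alt"] == "G")) | \
          ((alu["ref"] == "T") & (alu["alt"] == "C"))
    assert a2g.mean() > 0.95
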