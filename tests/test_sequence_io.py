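"""FASTA/GFF reading and strand-aware CDS extraction."""

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from phagekit.sequence_io import (
    CdsFeature,
    GenomeRecord,
    ValidationPolicy,
    extract_cds,
    read_fasta,
    read_gff_cds,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestReadFasta:
    def test_multiline_sequences_concatenated(self, fasta_file):
        recs = read_fasta(fasta_file(">g1\nACGT\nACGT\n"))
        assert len(recs) == 1
        assert recs[0].sequence == "ACGTACGT"
        assert recs[0].length == 8

    def test_records_in_file_order(self, fasta_file):
        recs = read_fasta(fasta_file(">b\nAAA\n>a\nCCC\n"))
        assert [r.id for r in recs] == ["b", "a"]

    def test_internal_whitespace_stripped(self, fasta_file):
        recs = read_fasta(fasta_file(">g1\nAC GT\n"))
        assert recs[0].sequence == "ACGT"

    def test_case_normalized_to_upper(self, fasta_file):
        recs = read_fasta(fasta_file(">g1\nacgtn\n"))
        assert recs[0].sequence == "ACGTN"

    def test_empty_file_errors(self, fasta_file):
        with pytest.raises(ValueError, match="no records"):
            read_fasta(fasta_file(""))

    def test_bad_character_names_record_and_position(self, fasta_file):
        with pytest.raises(ValueError, match=r"g1.*position 3"):
            read_fasta(fasta_file(">g1\nACXT\n"))


class TestReadGffCds:
    def test_only_cds_rows_consumed(self, gff_file):
        rows = [
            ("chr1", ".", "gene", 1, 100, ".", "+", ".", "ID=g1"),
            ("chr1", ".", "CDS", 3, 8, ".", "+", "0", "ID=c1"),
            ("chr1", ".", "CDS", 12, 20, ".", "-", "0", "ID=c2"),
            ("chr1", ".", "gene", 40, 90, ".", "+", ".", "ID=g2"),
            ("chr1", ".", "CDS", 50, 58, ".", "+", "0", "ID=c3"),
        ]
        feats = read_gff_cds(gff_file(rows))
        assert len(feats) == 3
        assert [f.feature_id for f in feats] == ["c1", "c2", "c3"]

    def test_coordinates_and_strand_preserved(self, gff_file):
        feats = read_gff_cds(gff_file([("chr1", ".", "CDS", 3, 8, ".", "+", "0", "ID=c1")]))
        f = feats[0]
        assert (f.start, f.end, f.strand) == (3, 8, "+")

    def test_multisegment_cds_joined(self, gff_file):
        rows = [
            ("chr1", ".", "CDS", 1, 6, ".", "+", "0", "ID=c1"),
            ("chr1", ".", "CDS", 10, 15, ".", "+", "0", "ID=c1"),
        ]
        feats = read_gff_cds(gff_file(rows))
        assert len(feats) == 1
        assert feats[0].parts == ((1, 6), (10, 15))
        assert feats[0].span == 12

    def test_seq_id_filter(self, gff_file):
        rows = [
            ("chr1", ".", "CDS", 1, 6, ".", "+", "0", "ID=a"),
            ("chr2", ".", "CDS", 1, 6, ".", "+", "0", "ID=b"),
        ]
        feats = read_gff_cds(gff_file(rows), seq_id_filter="chr2")
        assert [f.feature_id for f in feats] == ["b"]

    def test_start_after_end_errors(self, gff_file):
        with pytest.raises(ValueError, match="start"):
            read_gff_cds(gff_file([("chr1", ".", "CDS", 8, 3, ".", "+", "0", "ID=c1")]))

    def test_bad_strand_errors(self, gff_file):
        with pytest.raises(ValueError, match="strand"):
            read_gff_cds(gff_file([("chr1", ".", "CDS", 3, 8, ".", ".", "0", "ID=c1")]))


class TestExtractCds:
    def test_plus_strand_slice(self, tiny_genome):
        feat = CdsFeature("g1", 3, 8, "+", "f1")
        cds = extract_cds(tiny_genome, [feat])
        assert cds.cds_list == [("f1", "ATGCAT")]

    def test_minus_strand_is_reverse_complement(self, tiny_genome):
        # independent oracle: Biopython reverse complement of the + slice
        feat = CdsFeature("g1", 3, 8, "-", "f1")
        cds = extract_cds(tiny_genome, [feat])
        expected = str(Seq(tiny_genome.sequence[2:8]).reverse_complement())
        assert cds.cds_list == [("f1", expected)]
        assert expected == "ATGCAT"  # this slice is its own reverse complement

    def test_non_multiple_of_three_dropped(self, tiny_genome, caplog):
        feats = [CdsFeature("g1", 1, 4, "+", "bad"), CdsFeature("g1", 3, 8, "+", "good")]
        with caplog.at_level("INFO"):
            cds = extract_cds(tiny_genome, feats)
        assert [fid for fid, _ in cds.cds_list] == ["good"]
        assert any("DROPPED bad" in r.getMessage() for r in caplog.records)

    def test_internal_stop_dropped_by_default(self):
        g = GenomeRecord("g1", "ATGTAAAAATAG")
        with pytest.raises(ValueError, match="no valid CDS"):
            extract_cds(g, [CdsFeature("g1", 1, 12, "+", "f1")])
        keep = ValidationPolicy(drop_internal_stop=False)
        cds = extract_cds(g, [CdsFeature("g1", 1, 12, "+", "f1")], keep)
        assert cds.cds_list[0][1] == "ATGTAAAAATAG"

    def test_ambiguity_codes_dropped_by_default(self):
        g = GenomeRecord("g1", "ATGNNNAAATAG")
        with pytest.raises(ValueError, match="no valid CDS"):
            extract_cds(g, [CdsFeature("g1", 1, 12, "+", "f1")])

    def test_final_stop_strippable_by_policy(self):
        g = GenomeRecord("g1", "ATGAAATAG")
        cds = extract_cds(g, [CdsFeature("g1", 1, 9, "+", "f1")],
                          ValidationPolicy(keep_final_stop=False))
        assert cds.cds_list[0][1] == "ATGAAA"

    def test_partial_phase_dropped_by_default(self):
        g = GenomeRecord("g1", "ATGAAACCCTAG")
        feats = [CdsFeature("g1", 1, 12, "+", "p", phase=1),
                 CdsFeature("g1", 1, 12, "+", "full", phase=0)]
        cds = extract_cds(g, feats)
        assert [fid for fid, _ in cds.cds_list] == ["full"]

    def test_out_of_bounds_errors(self, tiny_genome):
        with pytest.raises(ValueError, match="out of bounds"):
            extract_cds(tiny_genome, [CdsFeature("g1", 5, 11, "+", "f1")])

    def test_multisegment_join_hand_computed(self):
        #        123456789012345
        g = GenomeRecord("g1", "ATGAAACCCGGGTTT")
        feat = CdsFeature("g1", 1, 15, "+", "c1", parts=((1, 6), (10, 15)))
        cds = extract_cds(g, [feat])
        assert cds.cds_list[0][1] == "ATGAAA" + "GGGTTT"

    def test_multisegment_minus_strand(self):
        # reading order on minus strand: downstream slice first, each revcomp'd
        g = GenomeRecord("g1", "ATGAAACCCGGGTTT")
        feat = CdsFeature("g1", 1, 15, "-", "c1", parts=((1, 6), (10, 15)))
        cds = extract_cds(g, [feat])
        expected = str(Seq("GGGTTT").reverse_complement()) + str(Seq("ATGAAA").reverse_complement())
        assert cds.cds_list[0][1] == expected

    def test_dropped_plus_retained_equals_input(self, tiny_genome):
        feats = [
            CdsFeature("g1", 3, 8, "+", "ok1"),
            CdsFeature("g1", 1, 4, "+", "bad"),
            CdsFeature("g1", 3, 8, "-", "ok2"),
        ]
        cds = extract_cds(tiny_genome, feats)
        assert len(cds) + (len(feats) - len(cds)) == len(feats)
        assert len(cds) == 2


class TestRoundTrip:
    def test_cds_fasta_round_trip(self, tmp_path, tiny_genome):
        feats = [CdsFeature("g1", 3, 8, "+", "f1"), CdsFeature("g1", 3, 8, "-", "f2")]
        cds = extract_cds(tiny_genome, feats)
        out = tmp_path / "cds.fasta"
        cds.to_fasta(out)
        back = read_fasta(out)
        assert [(r.id, r.sequence) for r in back] == cds.cds_list


@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@given(dna)
def test_reverse_complement_matches_biopython(seq):
    assert reverse_complement(seq) == str(Seq(seq).reverse_complement())


@given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=20))
def test_minus_extraction_equals_revcomp_of_plus(start_offset, length3):
    # build a genome long enough, compare strand extractions on one interval
    import numpy as np

    rng = np.random.default_rng(start_offset * 97 + length3)
    seq = "".join(rng.choice(list("ACGT"), size=start_offset + 3 * (length3 + 2) + 5))
    g = GenomeRecord("g", seq)
    start = start_offset
    end = start_offset + 3 * (length3 + 2) - 1  # 1-based inclusive, multiple of 3
    policy = ValidationPolicy(drop_internal_stop=False)
    plus = extract_cds(g, [CdsFeature("g", start, end, "+", "f")], policy)
    minus = extract_cds(g, [CdsFeature("g", start, end, "-", "f")], policy)
    assert minus.cds_list[0][1] == reverse_complement(plus.cds_list[0][1])
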