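"""Genome/annotation/TSS input handling and promoter extraction."""

import pytest
from hypothesis import given, settings, strategies as st

from phar_regulon import (
    GeneAnnotation,
    GenomeSequence,
    TSSRecord,
    extract_promoter,
    load_annotations,
    load_genome,
    load_tss,
    reverse_complement,
)


class TestLoadGenome:
    def test_single_record(self, tiny_fasta):
        genome = load_genome(tiny_fasta({"c1": "ACGT"}))
        assert list(genome) == ["c1"]
        assert genome["c1"].sequence == "ACGT"
        assert len(genome["c1"]) == 4

    def test_multi_record_mapping(self, tiny_fasta):
        genome = load_genome(tiny_fasta({"c1": "ACGT", "c2": "GGGG"}))
        assert set(genome) == {"c1", "c2"}

    def test_case_and_ambiguity_normalization(self, tiny_fasta):
        genome = load_genome(tiny_fasta({"c1": "acgtnRyx"}))
        assert genome["c1"].sequence == "ACGTNNNN"

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_genome(path)

    def test_duplicate_contig_is_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate contig id"):
            load_genome(path)


class TestLoadAnnotations:
    def test_tsv_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
            "blr2887\tc1\t100\t500\t+\tphasin\n"
        )
        genes = load_annotations(path)
        assert genes == [GeneAnnotation("blr2887", "c1", 100, 500, "+", "phasin")]
        assert genes[0].length == 401

    def test_coordinates_checked_against_genome(self, tmp_path, tiny_fasta):
        genome = load_genome(tiny_fasta({"c1": "ACGT" * 50}))
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
            "g1\tc1\t100\t500\t+\tx\n"
        )
        with pytest.raises(ValueError, match="beyond contig"):
            load_annotations(path, genome)

    def test_invalid_strand_reports_line(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
            "g1\tc1\t1\t10\t?\tx\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            load_annotations(path)

    def test_start_after_end_is_error(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\tcontig\tstart\tend\tstrand\tproduct\ng1\tc1\t50\t10\t+\tx\n"
        )
        with pytest.raises(ValueError):
            load_annotations(path)

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert load_annotations(path) == []

    def test_gff3_dialect(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t100\t500\t.\t+\t.\tID=g1;locus_tag=blr0001;product=phasin\n"
            "c1\t.\tgene\t700\t900\t.\t-\t.\tID=g2;locus_tag=blr0002\n"
        )
        genes = load_annotations(path)
        assert [g.gene_id for g in genes] == ["blr0001", "blr0002"]
        assert genes[1].strand == "-"


class TestTSS:
    def test_load_tss(self, tmp_path):
        path = tmp_path / "tss.tsv"
        path.write_text(
            "gene_id\tposition\tstrand\tsource\n"
            "g1\t95\t+\texperimental\n"
        )
        tss = load_tss(path)
        assert tss["g1"] == TSSRecord("g1", 95, "+", "experimental")

    def test_strand_must_match_gene(self):
        genome = {"c1": GenomeSequence("c1", "A" * 200)}
        gene = GeneAnnotation("g1", "c1", 100, 150, "+")
        with pytest.raises(ValueError, match="strand"):
            extract_promoter(gene, TSSRecord("g1", 95, "-"), genome, 10, 2)


class TestExtractPromoter:
    GENOME = {"c1": GenomeSequence("c1", "ACGTACGTAC" * 30)}  # 300 bp

    def test_plus_strand_window_arithmetic(self):
        gene = GeneAnnotation("g1", "c1", 100, 200, "+")
        tss = TSSRecord("g1", 100, "+")
        prom = extract_promoter(gene, tss, self.GENOME, upstream=10, downstream=2)
        assert (prom.start, prom.end) == (90, 102)
        assert len(prom) == 13
        assert prom.sequence == self.GENOME["c1"].sequence[89:102]

    def test_minus_strand_reverse_complemented(self):
        # place a distinctive 13-mer at genomic 98..110
        genome = {"c1": GenomeSequence("c1", "A" * 97 + "GTTGCAGGTCATG" + "A" * 90)}
        # anchor 100 on - strand, upstream 10, downstream 2 -> genomic 98..110
        gene = GeneAnnotation("g1", "c1", 50, 100, "-")
        tss = TSSRecord("g1", 100, "-")
        prom = extract_promoter(gene, tss, genome, upstream=10, downstream=2)
        assert (prom.start, prom.end) == (98, 110)
        genomic = genome["c1"].sequence[97:110]
        assert genomic == "GTTGCAGGTCATG"
        # manual reverse complement of the fixed 13-mer
        assert prom.sequence == "CATGACCTGCAAC"
        assert prom.sequence == reverse_complement(genomic)

    def test_degenerate_single_base_window(self):
        gene = GeneAnnotation("g1", "c1", 100, 200, "+")
        prom = extract_promoter(gene, None, self.GENOME, upstream=0, downstream=0)
        assert (prom.start, prom.end) == (100, 100)
        assert prom.anchor_source == "inferred_from_start_codon"
        assert len(prom) == 1

    def test_start_codon_anchor_minus_strand(self):
        gene = GeneAnnotation("g1", "c1", 100, 200, "-")
        prom = extract_promoter(gene, None, self.GENOME, upstream=10, downstream=2)
        assert prom.anchor == 200  # gene end is the start codon on -

    def test_truncation_flag_at_contig_edge(self):
        gene = GeneAnnotation("g1", "c1", 5, 50, "+")
        prom = extract_promoter(gene, None, self.GENOME, upstream=10, downstream=2)
        assert prom.truncated
        assert prom.start == 1

    def test_anchor_outside_contig_is_error(self):
        gene = GeneAnnotation("g1", "c1", 100, 200, "+")
        tss = TSSRecord("g1", 999, "+")
        with pytest.raises(ValueError, match="outside contig"):
            extract_promoter(gene, tss, self.GENOME, 10, 2)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_planted_promoter(self, strand):
        """A planted promoter sequence is recovered exactly on both strands."""
        planted = "TGCGACGCACAATTTGGCCAA"
        background = "ACGT" * 50
        if strand == "+":
            seq = background + planted + background
            anchor = len(background) + len(planted)  # 1-based end of planted
            gene = GeneAnnotation("g1", "c1", anchor + 10, anchor + 60, "+")
            tss = TSSRecord("g1", anchor, "+")
        else:
            seq = background + reverse_complement(planted) + background
            anchor = len(background) + 1
            gene = GeneAnnotation("g1", "c1", anchor - 60, anchor - 10, "-")
            tss = TSSRecord("g1", anchor, "-")
        genome = {"c1": GenomeSequence("c1", seq)}
        prom = extract_promoter(gene, tss, genome, upstream=len(planted) - 1, downstream=0)
        assert prom.sequence == planted


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=100))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
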