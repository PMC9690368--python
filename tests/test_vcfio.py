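"""VCF/GFF/BED/TSV round trips and rejection contracts."""

import numpy as np
import pytest

from sweepscan import CandidateRegion, ValidationError
from sweepscan.vcfio import (
    PhasingError,
    read_bed,
    read_gff,
    read_groups,
    read_sequence_regions,
    read_vcf,
    write_bed,
    write_gff,
    write_vcf,
)

from conftest import build_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVcf:
    def test_phased_genotypes_decode_to_haplotype_rows(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n")
        m, report = read_vcf(p)
        assert m.alleles[:, 0].tolist() == [0, 1, 1, 1]
        assert m.sample_ids == ["S1", "S2"]
        assert report.n_kept == 1 and not report.rejected

    def test_multiallelic_record_excluded_and_counted(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER
                  + "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
                  + "chr1\t200\t.\tA\tG,T\t.\t.\t.\tGT\t0|1\t1|1\n")
        m, report = read_vcf(p)
        assert m.n_variants == 1
        assert report.n_multiallelic == 1
        assert report.rejected == [("chr1", 200, "multiallelic")]

    def test_indel_excluded_as_non_snp(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER
                  + "chr1\t100\t.\tAT\tA\t.\t.\t.\tGT\t0|1\t1|1\n")
        m, report = read_vcf(p)
        assert m.n_variants == 0 and report.n_non_snp == 1

    def test_unphased_raises_naming_record_and_sample(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t300\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\n")
        with pytest.raises(PhasingError, match=r"S1.*chr1:300"):
            read_vcf(p, require_phased=True)
        m, _ = read_vcf(p, require_phased=False)
        assert not m.phased

    def test_missing_genotype_decoded(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t.|.\t1|1\n")
        m, _ = read_vcf(p)
        assert m.alleles[:, 0].tolist() == [-1, -1, 1, 1]


def test_vcf_round_trip_preserves_everything(tmp_path):
    rng = np.random.default_rng(3)
    rows = rng.integers(0, 2, size=(10, 20)).tolist()
    m = build_matrix(rows)
    path = tmp_path / "rt.vcf"
    write_vcf(m, path, contig_lengths={"chr1": 10_000})
    back, report = read_vcf(path)
    np.testing.assert_array_equal(m.alleles, back.alleles)
    assert m.sample_ids == back.sample_ids
    assert [v.pos for v in m.variants] == [v.pos for v in back.variants]
    assert report.n_kept == 20


class TestReadGroups:
    def test_two_by_two_split(self, tmp_path, tiny_matrix):
        p = write(tmp_path, "g.tsv",
                  "sample_id\tcontrast\trole\n"
                  "S0\tnap_size\ttest\nS1\tnap_size\ttest\n"
                  "S2\tnap_size\tcontrol\nS3\tnap_size\tcontrol\n")
        (gc,) = read_groups(p, tiny_matrix)
        assert gc.name == "nap_size"
        assert len(gc.test_samples) == len(gc.control_samples) == 2

    def test_sample_in_both_roles_rejected(self, tmp_path, tiny_matrix):
        p = write(tmp_path, "g.tsv",
                  "sample_id\tcontrast\trole\n"
                  "S0\tc\ttest\nS0\tc\tcontrol\nS1\tc\tcontrol\n")
        with pytest.raises(ValidationError, match="both roles"):
            read_groups(p, tiny_matrix)

    def test_empty_control_rejected(self, tmp_path, tiny_matrix):
        p = write(tmp_path, "g.tsv",
                  "sample_id\tcontrast\trole\nS0\tc\ttest\nS1\tc\ttest\n")
        with pytest.raises(ValidationError, match="nonempty"):
            read_groups(p, tiny_matrix)

    def test_unknown_sample_rejected(self, tmp_path, tiny_matrix):
        p = write(tmp_path, "g.tsv",
                  "sample_id\tcontrast\trole\nS0\tc\ttest\nZZ\tc\tcontrol\n")
        with pytest.raises(ValidationError, match="ZZ"):
            read_groups(p, tiny_matrix)


class TestGff:
    def test_gene_feature_parsed(self, tmp_path):
        p = write(tmp_path, "a.gff3", "##gff-version 3\n"
                  "chr3\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n")
        (g,) = read_gff(p)
        assert (g.chrom, g.start, g.end, g.gene_id) == ("chr3", 100, 200, "g1")

    def test_non_gene_features_ignored(self, tmp_path):
        p = write(tmp_path, "a.gff3", "##gff-version 3\n"
                  "chr3\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=rna1\n"
                  "chr3\tsrc\texon\t100\t150\t.\t+\t.\tID=e1;Parent=rna1\n")
        assert read_gff(p) == []

    def test_two_chromosomes_order_preserved(self, tmp_path):
        p = write(tmp_path, "a.gff3", "##gff-version 3\n"
                  "chr5\tsrc\tgene\t10\t20\t.\t-\t.\tID=g1\n"
                  "chr2\tsrc\tgene\t30\t40\t.\t+\t.\tID=g2\n")
        genes = read_gff(p)
        assert [g.gene_id for g in genes] == ["g1", "g2"]
        assert genes[0].strand == "-"

    def test_inverted_span_rejected(self, tmp_path):
        p = write(tmp_path, "a.gff3", "##gff-version 3\n"
                  "chr3\tsrc\tgene\t200\t100\t.\t+\t.\tID=bad\n")
        with pytest.raises(ValidationError, match="bad"):
            read_gff(p)

    def test_sequence_region_pragmas(self, tmp_path):
        p = write(tmp_path, "a.gff3", "##gff-version 3\n"
                  "##sequence-region chr1 1 5000\n"
                  "##sequence-region chr2 1 7000\n"
                  "chr1\tsrc\tgene\t10\t20\t.\t+\t.\tID=g1\n")
        assert read_sequence_regions(p) == {"chr1": 5000, "chr2": 7000}

    def test_gff_to_bed_round_trip_preserves_span(self, tmp_path):
        gff = tmp_path / "g.gff3"
        write_gff([_gene("chr7", 1234, 5678)], gff)
        (g,) = read_gff(gff)
        bed = tmp_path / "g.bed"
        write_bed([CandidateRegion(chrom=g.chrom, start=g.start, end=g.end,
                                   contrast="c", support="2way")], bed)
        (r,) = read_bed(bed)
        assert (r.start, r.end) == (1234, 5678)


def _gene(chrom, start, end):
    from sweepscan import GeneModel
    return GeneModel(gene_id="g", chrom=chrom, start=start, end=end, strand="+")


class TestWriteBed:
    def test_coordinate_convention(self, tmp_path):
        r = CandidateRegion(chrom="8", start=26_111_849, end=26_121_849,
                            contrast="Nap size", support="3way",
                            genes=("CCM2L",))
        p = tmp_path / "r.bed"
        write_bed([r], p)
        fields = p.read_text().strip().split("\t")
        assert fields[:3] == ["8", "26111848", "26121849"]
        assert fields[3:] == ["Nap size", "CCM2L"]

    def test_empty_region_list(self, tmp_path):
        p = tmp_path / "r.bed"
        write_bed([], p)
        assert p.read_text() == ""

    def test_writer_does_not_merge(self, tmp_path):
        rs = [CandidateRegion(chrom="1", start=100, end=300, contrast="a",
                              support="2way"),
              CandidateRegion(chrom="1", start=200, end=400, contrast="b",
                              support="2way")]
        p = tmp_path / "r.bed"
        write_bed(rs, p)
        assert len(p.read_text().strip().splitlines()) == 2
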