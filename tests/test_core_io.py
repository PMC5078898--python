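"""Domain types and text-format round trips."""

import numpy as np
import pandas as pd
import pytest

from dipseq import io
from dipseq.genome import (GeneModel, Genome, GenomicInterval, TagSet,
                           merge_intervals)


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_one_based_conversion_round_trips(self):
        iv = GenomicInterval("chr1", 99, 200)
        assert iv.to_one_based_closed() == ("chr1", 100, 200)
        assert GenomicInterval.from_one_based_closed(*iv.to_one_based_closed()) == iv

    def test_merge_handles_overlap_and_bookend(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20),
               GenomicInterval("chr1", 5, 12), GenomicInterval("chr1", 30, 40)]
        assert merge_intervals(ivs) == [GenomicInterval("chr1", 0, 20),
                                        GenomicInterval("chr1", 30, 40)]


class TestGenomeAndTagSet:
    def test_genome_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            Genome({"chr1": 0})

    def test_tag_positions_validated_against_genome(self, genome):
        with pytest.raises(ValueError, match="outside chromosome"):
            TagSet("s", "5mC", "sham", genome, {"chr1": np.array([2_000])})
        with pytest.raises(ValueError, match="unknown chromosome"):
            TagSet("s", "5mC", "sham", genome, {"chrX": np.array([5])})

    def test_library_size_counts_all_tags(self, make_tags):
        tags = make_tags({"chr1": [5, 5, 100], "chr2": [0]})
        assert tags.library_size == 4
        assert tags.collapse_duplicates().library_size == 3

    def test_interval_counting_is_half_open(self, make_tags):
        tags = make_tags({"chr1": [99, 100, 199, 200]})
        assert tags.count_in(GenomicInterval("chr1", 100, 200)) == 2


class TestTagIO:
    def test_bed_records_become_tags(self, tmp_path, genome):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t10\t60\nchr1\t20\t70\nchr2\t5\t55\t.\t0\t-\n")
        tags = io.read_tags(path, genome, "5mC", "sham")
        assert tags.library_size == 3
        assert list(tags.positions_on("chr1")) == [10, 20]
        assert tags.strands_on("chr2")[0] == "-"

    def test_empty_file_gives_empty_tagset(self, tmp_path, genome):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert io.read_tags(path, genome, "5mC", "sham").library_size == 0

    def test_out_of_bounds_start_is_rejected(self, tmp_path, genome):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t2000\t2050\n")
        with pytest.raises(ValueError, match="beyond end"):
            io.read_tags(path, genome, "5mC", "sham")

    def test_malformed_line_names_line_number(self, tmp_path, genome):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t60\nchr1\tnothing\n")
        with pytest.raises(io.ParseError, match=":2"):
            io.read_tags(path, genome, "5mC", "sham")

    def test_write_read_round_trip(self, tmp_path, make_tags):
        tags = make_tags({"chr1": [3, 3, 1999], "chr2": [0, 4999]})
        path = tmp_path / "rt.bed"
        io.write_tags(tags, path)
        back = io.read_tags(path, tags.genome, tags.assay, tags.condition)
        for chrom in tags.chroms:
            assert np.array_equal(tags.positions_on(chrom),
                                  back.positions_on(chrom))


class TestGeneModelIO:
    def test_single_exon_plus_strand(self, simple_gene):
        assert simple_gene.tss == 100
        assert simple_gene.mappable_length == 500

    def test_minus_strand_tss_is_end_minus_one(self):
        g = GeneModel("g", "chr1", "-", 100, 600)
        assert g.tss == 599

    def test_two_exons_sum_mappable_length(self):
        g = GeneModel("g", "chr1", "+", 0, 300,
                      (GenomicInterval("chr1", 0, 100),
                       GenomicInterval("chr1", 200, 300)))
        assert g.mappable_length == 200

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping exons"):
            GeneModel("g", "chr1", "+", 0, 300,
                      (GenomicInterval("chr1", 0, 150),
                       GenomicInterval("chr1", 100, 300)))

    def test_bed12_round_trip(self, tmp_path, rng):
        genes = []
        for i in range(20):
            start = int(rng.integers(0, 5000))
            length = int(rng.integers(300, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            mid = start + length // 2
            exons = (GenomicInterval("chr3", start, mid - 10),
                     GenomicInterval("chr3", mid, start + length))
            genes.append(GeneModel(f"g{i}", "chr3", strand, start,
                                   start + length, exons))
        path = tmp_path / "genes.bed12"
        io.write_gene_models(genes, path)
        back = io.read_gene_models(path)
        assert sorted(back, key=lambda g: g.gene_id) == \
            sorted(genes, key=lambda g: g.gene_id)

    def test_refflat_parsing(self, tmp_path):
        line = ("sym\tg1\tchr1\t-\t100\t600\t100\t600\t2\t100,400,\t200,600,\n")
        path = tmp_path / "genes.refflat"
        path.write_text(line)
        (g,) = io.read_gene_models(path)
        assert g.gene_id == "g1" and g.strand == "-" and g.tss == 599
        assert g.mappable_length == 300

    def test_inconsistent_blocks_rejected(self, tmp_path):
        path = tmp_path / "bad.bed12"
        path.write_text("chr1\t0\t500\tg\t0\t+\t0\t500\t0\t2\t100,\t0,\n")
        with pytest.raises(io.ParseError, match="blockCount"):
            io.read_gene_models(path)


class TestRegionIO:
    def test_round_trip_preserves_overlaps_and_scores(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 50, 0],
            "end": [200, 150, 10],
            "p": [0.1, 0.02, 1.0],
        })
        path = tmp_path / "regions.tsv"
        io.write_regions(df, path)
        back = io.read_regions(path)
        # sorted on write, all rows preserved (overlap not merged)
        assert len(back) == 3
        assert back.iloc[0]["start"] == 50
        assert set(back["p"]) == {0.1, 0.02, 1.0}

    def test_empty_table_round_trips(self, tmp_path):
        df = pd.DataFrame(columns=["chrom", "start", "end", "p"])
        path = tmp_path / "empty.tsv"
        io.write_regions(df, path)
        assert len(io.read_regions(path)) == 0

    def test_missing_columns_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="chrom"):
            io.write_regions(pd.DataFrame({"a": [1]}), tmp_path / "x.tsv")
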