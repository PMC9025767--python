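import random

import numpy as np
import pytest

from repliconkit import (
    AnnotationRecord,
    CoverageTrack,
    GenomeSet,
    Replicon,
    Role,
    gc_percent,
    read_depth,
    read_gff,
    read_replicons,
    tokenize_labels,
    write_gff,
    write_replicons,
)


def _count_gc_oracle(seq):
    counts = {b: seq.count(b) for b in "ACGTN"}
    denom = sum(counts[b] for b in "ACGT")
    return 100.0 * (counts["G"] + counts["C"]) / denom if denom else 0.0


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 50.0), ("GGCC", 100.0), ("AT", 0.0), ("NNGC", 100.0)],
    )
    def test_known_compositions(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    def test_matches_single_pass_counter_on_random_sequences(self):
        rng = random.Random(42)
        for _ in range(20):
            seq = "".join(rng.choice("ACGTN") for _ in range(rng.randint(10, 500)))
            assert gc_percent(seq) == pytest.approx(_count_gc_oracle(seq))

    def test_plasmid_scale_rounding(self):
        # 6,732 bp with 3,507 G+C reports GC 52.1 at one decimal place
        seq = "G" * 1753 + "C" * 1754 + "A" * 1612 + "T" * 1613
        assert len(seq) == 6732
        assert round(gc_percent(seq), 1) == 52.1


class TestGenomeSet:
    def test_requires_exactly_one_chromosome(self):
        reps = [Replicon("a", "ACGT", Role.ECR)]
        with pytest.raises(ValueError, match="chromosome"):
            GenomeSet("g", reps)

    def test_annotation_bounds_checked(self):
        reps = [Replicon("c", "ACGTACGT", Role.CHROMOSOME)]
        genome = GenomeSet("g", reps)
        with pytest.raises(ValueError, match="exceeds length"):
            genome.add_annotations(
                [AnnotationRecord("c", 5, 20, "+", "CDS", frozenset())]
            )

    def test_coverage_length_checked(self):
        genome = GenomeSet("g", [Replicon("c", "ACGTACGT", Role.CHROMOSOME)])
        with pytest.raises(ValueError, match="positions"):
            genome.add_coverage(CoverageTrack("c", np.ones(5)))


class TestFastaIO:
    def test_round_trip_preserves_ids_and_sequences(self, tmp_path):
        genome = GenomeSet(
            "g",
            [
                Replicon("chr1", "ACGTACGTNN", Role.CHROMOSOME),
                Replicon("p1", "GGGCCCAATT", Role.ECR),
            ],
        )
        path = tmp_path / "g.fasta"
        write_replicons(genome, path)
        back = read_replicons(path, chromosome_id="chr1")
        assert [r.id for r in back.replicons] == ["chr1", "p1"]
        assert [r.sequence for r in back.replicons] == [
            "ACGTACGTNN", "GGGCCCAATT",
        ]
        assert back.chromosome.id == "chr1"

    def test_missing_chromosome_id_is_configuration_error(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">a\nACGT\n")
        with pytest.raises(ValueError, match="chromosome id"):
            read_replicons(path, chromosome_id="nope")

    def test_lowercase_input_uppercased(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">a\nacgt\n")
        genome = read_replicons(path, chromosome_id="a")
        assert genome.chromosome.sequence == "ACGT"


class TestGFF:
    def test_product_tokenized_lowercase(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n"
            "r1\tsrc\tCDS\t10\t99\t.\t+\t0\tID=x;product=ParA family protein\n"
        )
        records = read_gff(path)
        assert len(records) == 1
        assert "para" in records[0].labels
        assert records[0].start == 10 and records[0].end == 99

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        assert read_gff(path) == []

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("r1\tsrc\tCDS\t99\t10\t.\t+\t0\tID=x\n")
        with pytest.raises(ValueError, match="interval"):
            read_gff(path)

    def test_round_trip(self, tmp_path):
        records = [
            AnnotationRecord("r1", 1, 90, "+", "CDS",
                             tokenize_labels("ParB family protein")),
            AnnotationRecord("r1", 100, 250, "-", "CDS",
                             tokenize_labels("MobQ family relaxase")),
        ]
        path = tmp_path / "rt.gff3"
        write_gff(records, path, products={0: "ParB family protein",
                                           1: "MobQ family relaxase"})
        back = read_gff(path)
        assert [(r.start, r.end, r.strand) for r in back] == [
            (1, 90, "+"), (100, 250, "-"),
        ]
        assert back[0].labels == records[0].labels
        assert back[1].labels == records[1].labels


class TestDepthTSV:
    def test_dense_track(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("r1\t1\t10\nr1\t2\t12\n")
        tracks = read_depth(path)
        assert tracks["r1"].depths.tolist() == [10, 12]

    def test_missing_positions_filled_with_zero(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("r1\t1\t10\nr1\t3\t12\n")
        tracks = read_depth(path)
        assert tracks["r1"].depths.tolist() == [10, 0, 12]

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("r1\t1\t10\nr1\t1\t11\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_depth(path)

    def test_position_beyond_replicon_length_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("r1\t5\t10\n")
        with pytest.raises(ValueError, match="exceeds length"):
            read_depth(path, lengths={"r1": 3})
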