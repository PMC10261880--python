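import math

import pytest
from Bio import SeqIO

from slow5pipe import (
    mean_qscore,
    read_fastq,
    read_sam,
    split_by_qscore,
    split_qscore_tool,
    write_fastq,
    write_sam,
)
from slow5pipe.model import BasecallResult
from slow5pipe.writers import RecordFormatError, decode_qualities, encode_qualities


def result(read_id, seq, quals):
    return BasecallResult(read_id, seq, tuple(quals), mean_qscore(quals))


@pytest.fixture()
def mixed_results():
    return [
        result("r_low", "ACGT", [3, 4, 5, 6]),        # mean ~ 4.4
        result("r_edge", "ACGT", [7, 7, 7, 7]),       # mean exactly 7.0
        result("r_high", "ACGTAC", [30, 32, 35, 40, 28, 33]),
        result("r_mid", "AC", [10, 12]),
    ]


class TestEncoding:
    def test_phred33_example(self, tmp_path):
        path = tmp_path / "one.fastq"
        write_fastq([result("r1", "ACGT", [10, 10, 10, 10])], path)
        lines = path.read_text().splitlines()
        assert lines == ["@r1", "ACGT", "+", "++++"]

    def test_round_trip_all_encodable_values(self):
        quals = list(range(0, 94))
        assert list(decode_qualities(encode_qualities(quals))) == quals

    def test_out_of_range_clamped(self):
        assert decode_qualities(encode_qualities([-3, 100])) == (0, 93)

    def test_biopython_parses_our_fastq(self, tmp_path, mixed_results):
        """Independent parser oracle for the 4-line writer."""
        path = tmp_path / "oracle.fastq"
        write_fastq(mixed_results, path)
        parsed = list(SeqIO.parse(str(path), "fastq"))
        assert [p.id for p in parsed] == [r.read_id for r in mixed_results]
        for rec, res in zip(parsed, mixed_results):
            assert str(rec.seq) == res.sequence
            assert tuple(rec.letter_annotations["phred_quality"]) == res.qualities


class TestFormatEquivalence:
    def test_empty_outputs(self, tmp_path):
        fq, sam = tmp_path / "e.fastq", tmp_path / "e.sam"
        assert write_fastq([], fq) == 0
        assert write_sam([], sam) == 0
        assert fq.read_text() == ""
        assert all(l.startswith("@") for l in sam.read_text().splitlines())

    def test_fastq_sam_content_identical(self, tmp_path, mixed_results):
        fq, sam = tmp_path / "x.fastq", tmp_path / "x.sam"
        write_fastq(mixed_results, fq)
        write_sam(mixed_results, sam)
        a = [(r.read_id, r.sequence, r.qualities) for r in read_fastq(fq)]
        b = [(r.read_id, r.sequence, r.qualities) for r in read_sam(sam)]
        assert a == b

    def test_sam_records_unmapped_with_qscore_tags(self, tmp_path, mixed_results):
        sam = tmp_path / "u.sam"
        write_sam(mixed_results, sam)
        for line in sam.read_text().splitlines():
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            assert fields[1] == "4" and fields[2] == "*" and fields[5] == "*"
            assert any(f.startswith("qs:i:") for f in fields[11:])
            assert any(f.startswith("mq:f:") for f in fields[11:])

    def test_sam_mean_qscore_tag_round_trips(self, tmp_path, mixed_results):
        sam = tmp_path / "t.sam"
        write_sam(mixed_results, sam)
        for back, orig in zip(read_sam(sam), mixed_results):
            assert back.mean_qscore == pytest.approx(orig.mean_qscore, abs=1e-4)


class TestSplitByQscore:
    def test_boundary_inclusive_partition(self, mixed_results):
        passed, failed = split_by_qscore(mixed_results, 7.0)
        assert {r.read_id for r in passed} == {"r_edge", "r_high", "r_mid"}
        assert {r.read_id for r in failed} == {"r_low"}
        assert len(passed) + len(failed) == len(mixed_results)

    def test_threshold_extremes(self, mixed_results):
        assert len(split_by_qscore(mixed_results, 0.0)[0]) == len(mixed_results)
        assert len(split_by_qscore(mixed_results, math.inf)[1]) == len(mixed_results)

    def test_records_unaltered(self, mixed_results):
        passed, failed = split_by_qscore(mixed_results, 7.0)
        assert sorted(passed + failed, key=lambda r: r.read_id) == \
            sorted(mixed_results, key=lambda r: r.read_id)


class TestSplitTool:
    @pytest.mark.parametrize("fmt,writer", [("fastq", write_fastq), ("sam", write_sam)])
    def test_partition_counts_and_byte_identity(self, tmp_path, mixed_results, fmt, writer):
        src = tmp_path / f"in.{fmt}"
        writer(mixed_results, src)
        n_pass, n_fail = split_qscore_tool(str(src), 7.0, str(tmp_path / "out"))
        assert (n_pass, n_fail) == (3, 1)
        merged = (tmp_path / f"out.pass.{fmt}").read_text() + \
                 (tmp_path / f"out.fail.{fmt}").read_text()
        for line in src.read_text().splitlines():
            assert line in merged  # routing copies records verbatim

    def test_pass_file_resplit_is_idempotent(self, tmp_path, mixed_results):
        src = tmp_path / "in.fastq"
        write_fastq(mixed_results, src)
        split_qscore_tool(str(src), 7.0, str(tmp_path / "s1"))
        n_pass, n_fail = split_qscore_tool(
            str(tmp_path / "s1.pass.fastq"), 7.0, str(tmp_path / "s2")
        )
        assert (n_pass, n_fail) == (3, 0)
        assert (tmp_path / "s1.pass.fastq").read_bytes() == \
            (tmp_path / "s2.pass.fastq").read_bytes()

    def test_all_plus_qualities_pass_at_ten(self, tmp_path):
        src = tmp_path / "plus.fastq"
        src.write_text("@p1\nACGT\n+\n++++\n")
        n_pass, n_fail = split_qscore_tool(str(src), 10.0, str(tmp_path / "p"))
        assert (n_pass, n_fail) == (1, 0)  # '+' encodes q=10; mean 10 >= 10

    def test_sam_trusts_tag_unless_recompute(self, tmp_path):
        src = tmp_path / "tag.sam"
        src.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t++++\tqs:i:3\tmq:f:3.0\n"
        )
        # stored tag (3) fails at 7; recomputed mean ('+' = q10) passes
        assert split_qscore_tool(str(src), 7.0, str(tmp_path / "a")) == (0, 1)
        assert split_qscore_tool(str(src), 7.0, str(tmp_path / "b"),
                                 recompute=True) == (1, 0)

    def test_malformed_record_cleans_outputs(self, tmp_path):
        src = tmp_path / "bad.fastq"
        src.write_text("@r1\nACGT\n+\n++++\n@r2\nACG\n")
        with pytest.raises(RecordFormatError):
            split_qscore_tool(str(src), 7.0, str(tmp_path / "bad"))
        assert not (tmp_path / "bad.pass.fastq").exists()
        assert not (tmp_path / "bad.fail.fastq").exists()
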