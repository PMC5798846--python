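"""Read preprocessing and SAM ingestion."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapscreen.sequence_io import (AlignedFlank, FastqFormatError, RawRead,
                                   load_alignments, preprocess_reads,
                                   read_fastq, write_fastq)
from oracles import cigar_reference_span


def fastq_text(records):
    return "".join(
        f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in records
    )


def q(scores):
    return "".join(chr(s + 33) for s in scores)


class TestFastqIO:
    def test_roundtrip(self):
        text = fastq_text([("r1", "ACGT", q([30, 30, 20, 10])), ("r2", "NNN", "III")])
        reads = list(read_fastq(io.StringIO(text)))
        assert [r.id for r in reads] == ["r1", "r2"]
        assert reads[0].qualities == (30, 30, 20, 10)
        out = io.StringIO()
        assert write_fastq(reads, out) == 2
        assert out.getvalue() == text

    def test_malformed_record_names_index(self):
        # second record is truncated after its sequence line
        text = "@r1\nACGT\n+\n" + q([30] * 4) + "\n@r2\nACGT\n"
        with pytest.raises(FastqFormatError, match="index 1"):
            list(read_fastq(io.StringIO(text)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            RawRead("r", "ACGT", (30, 30))


class TestPreprocessReads:
    def make(self, seq, quals, rid="r"):
        return RawRead(rid, seq, tuple(quals))

    def test_clean_read_unchanged(self):
        read = self.make("A" * 40, [30] * 40)
        out = list(preprocess_reads([read], adaptor="CCCGGG", min_length=26))
        assert out == [read]

    def test_adaptor_trimmed_read_dropped_below_min_length(self):
        # 30 nt read whose last 10 nt are the adaptor prefix: 20 nt remain
        adaptor = "GATCGGAAGAGCACACGTCT"
        seq = "A" * 20 + adaptor[:10]
        read = self.make(seq, [35] * 30)
        assert list(preprocess_reads([read], adaptor=adaptor, min_length=26)) == []
        kept = list(preprocess_reads([read], adaptor=adaptor, min_length=20))
        assert kept[0].sequence == "A" * 20

    def test_adaptor_match_tolerates_mismatches(self):
        adaptor = "GATCGGAAGA"
        suffix = "GATCGGAAGT"  # 1 mismatch in 10 = 10%
        read = self.make("C" * 30 + suffix, [35] * 40)
        kept = list(preprocess_reads([read], adaptor=adaptor, min_length=26))
        assert kept[0].sequence == "C" * 30

    def test_quality_trimming_removes_bad_tail(self):
        read = self.make("A" * 30 + "C" * 10, [35] * 30 + [2] * 10)
        kept = list(preprocess_reads([read], min_length=26, quality_cutoff=20))
        assert kept[0].sequence == "A" * 30

    def test_empty_stream(self):
        assert list(preprocess_reads([], adaptor="ACGT")) == []

    def test_order_preserved(self):
        reads = [self.make("A" * 30, [30] * 30, rid=f"r{i}") for i in range(5)]
        out = list(preprocess_reads(reads, min_length=26))
        assert [r.id for r in out] == [f"r{i}" for i in range(5)]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=60),
        quals=st.lists(st.integers(0, 41), min_size=60, max_size=60),
        adaptor=st.text(alphabet="ACGT", min_size=0, max_size=12),
    )
    def test_idempotent(self, seq, quals, adaptor):
        read = RawRead("r", seq, tuple(quals[: len(seq)]))
        once = list(preprocess_reads([read], adaptor=adaptor, min_length=1))
        twice = list(preprocess_reads(once, adaptor=adaptor, min_length=1))
        assert once == twice


def sam_text(records, sq=("chr1", 100_000)):
    header = f"@HD\tVN:1.6\n@SQ\tSN:{sq[0]}\tLN:{sq[1]}\n"
    return header + "".join(
        f"{name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\n"
        for name, flag, rname, pos, mapq, cigar in records
    )


class TestLoadAlignments:
    def load(self, text, tmp_path, min_mapq=10):
        path = tmp_path / "in.sam"
        path.write_text(text)
        return list(load_alignments(path, min_mapq=min_mapq))

    def test_forward_record_position_is_pos(self, tmp_path):
        flanks = self.load(sam_text([("r1", 0, "chr1", 1001, 42, "30M")]), tmp_path)
        assert flanks == [AlignedFlank("chr1", "+", 1001, 42)]

    def test_reverse_record_position_is_rightmost_base(self, tmp_path):
        flanks = self.load(sam_text([("r1", 16, "chr1", 1001, 42, "30M")]), tmp_path)
        assert flanks == [AlignedFlank("chr1", "-", 1030, 42)]

    def test_mapq_filter(self, tmp_path):
        text = sam_text([("r1", 0, "chr1", 500, 5, "30M"),
                         ("r2", 0, "chr1", 600, 10, "30M")])
        flanks = self.load(text, tmp_path, min_mapq=10)
        assert [f.position for f in flanks] == [600]
        assert all(f.mapq >= 10 for f in flanks)

    def test_unmapped_secondary_supplementary_skipped(self, tmp_path):
        text = sam_text([
            ("r1", 4, "*", 0, 0, "*"),
            ("r2", 256, "chr1", 700, 42, "30M"),
            ("r3", 2048, "chr1", 800, 42, "30M"),
            ("r4", 0, "chr1", 900, 42, "30M"),
        ])
        flanks = self.load(text, tmp_path)
        assert [f.position for f in flanks] == [900]

    def test_reference_free_cigar_skipped(self, tmp_path):
        text = sam_text([("r1", 0, "chr1", 500, 42, "30I"),
                         ("r2", 0, "chr1", 600, 42, "30M")])
        flanks = self.load(text, tmp_path)
        assert [f.position for f in flanks] == [600]

    def test_headerless_sam_is_parsed(self, tmp_path):
        body = "r1\t16\tchr1\t1001\t42\t30M\t*\t0\t0\t*\t*\n"
        path = tmp_path / "nohdr.sam"
        path.write_text(body)
        assert list(load_alignments(path)) == [AlignedFlank("chr1", "-", 1030, 42)]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        ops=st.lists(
            st.tuples(st.integers(1, 50), st.sampled_from("MIDNSX=")),
            min_size=1, max_size=6,
        ),
        pos=st.integers(1, 5000),
    )
    def test_reverse_position_matches_cigar_walk(self, tmp_path_factory, ops, pos):
        """Reverse-strand position = POS + reference span - 1 for any CIGAR."""
        # a valid alignment must start and end with a match and contain one
        ops = [(10, "M")] + ops + [(10, "M")]
        cigar = "".join(f"{n}{op}" for n, op in ops)
        span = cigar_reference_span(cigar)
        tmp = tmp_path_factory.mktemp("sam")
        path = tmp / "r.sam"
        path.write_text(sam_text([("r1", 16, "chr1", pos, 42, cigar)],
                                 sq=("chr1", 1_000_000)))
        (flank,) = load_alignments(path)
        assert flank.position == pos + span - 1

    def test_output_never_exceeds_input(self, tmp_path):
        records = [(f"r{i}", 0, "chr1", 100 + i, i % 60, "20M") for i in range(30)]
        flanks = self.load(sam_text(records), tmp_path, min_mapq=20)
        assert len(flanks) <= 30
        assert all(f.mapq >= 20 for f in flanks)
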