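import os

import numpy as np
import pytest

from slow5pipe import (
    MockModel,
    RunHeader,
    Slow5File,
    append_slow5,
    build_index,
    default_header,
    ensure_index,
    generate_reads,
    get_read,
    load_index,
    read_header,
    stream_reads,
    write_slow5,
)
from slow5pipe.io import (
    MAGIC,
    DuplicateReadIdError,
    HeaderMismatchError,
    MissingIndexError,
    ReadNotFoundError,
    Slow5ParseError,
    StaleIndexError,
)
from slow5pipe.model import AuxSchemaError, ValidationError


def reads_only(pairs):
    return [r for r, _ in pairs]


class TestRoundTrip:
    @pytest.mark.parametrize("binary", [False, True])
    def test_empty_file(self, tmp_path, model, binary):
        path = tmp_path / "empty"
        n = write_slow5(path, default_header(model), [], binary=binary)
        assert n == 0
        assert list(stream_reads(path)) == []
        assert read_header(path) == default_header(model)

    @pytest.mark.parametrize("record_codec", ["none", "zlib", "zstd"])
    @pytest.mark.parametrize("signal_codec", ["none", "delta_zigzag_varint"])
    def test_binary_codec_combinations(self, tmp_path, model, reads20,
                                       record_codec, signal_codec):
        header = RunHeader(
            attributes=default_header(model).attributes,
            aux_schema=default_header(model).aux_schema,
            record_codec=record_codec,
            signal_codec=signal_codec,
        )
        path = tmp_path / "c.blow5"
        write_slow5(path, header, reads_only(reads20), binary=True)
        assert list(stream_reads(path)) == reads_only(reads20)
        assert read_header(path) == header

    def test_cross_dialect_equivalence(self, blow5_file, slow5_file, reads20):
        assert list(stream_reads(blow5_file)) == list(stream_reads(slow5_file))
        assert list(stream_reads(blow5_file)) == reads_only(reads20)

    def test_writers_byte_deterministic(self, tmp_path, model, reads20):
        digests = []
        for name in ("a", "b"):
            for binary, ext in ((False, "slow5"), (True, "blow5")):
                p = tmp_path / f"{name}.{ext}"
                write_slow5(p, default_header(model), reads_only(reads20), binary=binary)
            digests.append((
                (tmp_path / f"{name}.slow5").read_bytes(),
                (tmp_path / f"{name}.blow5").read_bytes(),
            ))
        assert digests[0] == digests[1]

    def test_duplicate_read_id_rejected_and_file_removed(self, tmp_path, model, reads20):
        path = tmp_path / "dup.blow5"
        dup = reads_only(reads20)[:2] + reads_only(reads20)[:1]
        with pytest.raises(DuplicateReadIdError):
            write_slow5(path, default_header(model), dup, binary=True)
        assert not path.exists()

    def test_aux_schema_violation_rejected(self, tmp_path, model, reads20):
        read = reads_only(reads20)[0]
        bad = type(read)(
            read_id="x1", read_group=0, digitisation=read.digitisation,
            offset=read.offset, range=read.range, sampling_rate=read.sampling_rate,
            raw_signal=read.raw_signal, aux={},  # misses every schema field
        )
        with pytest.raises(AuxSchemaError):
            write_slow5(tmp_path / "bad.blow5", default_header(model), [bad], binary=True)

    def test_read_group_out_of_range_rejected(self, tmp_path, model, reads20):
        read = reads_only(reads20)[0]
        stray = type(read)(
            read_id="x2", read_group=5, digitisation=read.digitisation,
            offset=read.offset, range=read.range, sampling_rate=read.sampling_rate,
            raw_signal=read.raw_signal, aux=dict(read.aux),
        )
        with pytest.raises(ValidationError):
            write_slow5(tmp_path / "bad.blow5", default_header(model), [stray], binary=True)


class TestHeader:
    def test_multi_group_attribute_round_trip(self, tmp_path):
        header = RunHeader(
            num_read_groups=2,
            attributes=({"run_id": "a", "flow_cell": "FAL0"}, {"run_id": "b"}),
            aux_schema=(("channel_number", "int"),),
        )
        path = tmp_path / "h.blow5"
        write_slow5(path, header, [], binary=True)
        back = read_header(path)
        assert back == header
        assert list(back.attributes[0]) == ["run_id", "flow_cell"]  # order kept

    def test_corrupt_magic_named_in_error(self, tmp_path, blow5_file):
        data = bytearray(open(blow5_file, "rb").read())
        data[:4] = b"XXXX"
        bad = tmp_path / "bad.blow5"
        bad.write_bytes(bytes(data))
        with pytest.raises(Slow5ParseError, match="magic"):
            read_header(bad)

    def test_unsupported_version(self, tmp_path, blow5_file):
        data = bytearray(open(blow5_file, "rb").read())
        data[8:10] = (99).to_bytes(2, "little")
        bad = tmp_path / "v99.blow5"
        bad.write_bytes(bytes(data))
        with pytest.raises(Slow5ParseError, match="version"):
            read_header(bad)

    def test_truncated_header(self, tmp_path, blow5_file):
        bad = tmp_path / "trunc.blow5"
        bad.write_bytes(open(blow5_file, "rb").read()[:12])
        with pytest.raises(Slow5ParseError, match="[Tt]runcated"):
            read_header(bad)


class TestAppend:
    def test_append_zero_reads_is_bitwise_noop(self, blow5_file):
        before = open(blow5_file, "rb").read()
        total = append_slow5(blow5_file, [])
        assert total == 20
        assert open(blow5_file, "rb").read() == before

    @pytest.mark.parametrize("binary", [False, True])
    def test_write_then_append_preserves_prefix_and_order(self, tmp_path, model, binary):
        first = generate_reads(2, 30, model)
        second = generate_reads(3, 30, MockModel(seed=5), id_start=2)
        path = tmp_path / "app"
        write_slow5(path, default_header(model), reads_only(first), binary=binary)
        before = open(path, "rb").read()
        total = append_slow5(path, reads_only(second))
        assert total == 5
        after = open(path, "rb").read()
        assert after[: len(before)] == before
        ids = [r.read_id for r in stream_reads(path)]
        assert ids == [r.read_id for r in reads_only(first) + reads_only(second)]

    def test_append_collision_rejected(self, blow5_file, reads20):
        with pytest.raises(DuplicateReadIdError):
            append_slow5(blow5_file, reads_only(reads20)[:1])

    def test_append_schema_violation_rejected(self, blow5_file, reads20):
        r = reads_only(reads20)[0]
        incomplete = type(r)(
            read_id="new_read", read_group=0, digitisation=r.digitisation,
            offset=r.offset, range=r.range, sampling_rate=r.sampling_rate,
            raw_signal=r.raw_signal, aux={"channel_number": 1},  # other fields missing
        )
        with pytest.raises(AuxSchemaError):
            append_slow5(blow5_file, [incomplete])

    def test_append_header_mismatch_rejected(self, blow5_file):
        with pytest.raises(HeaderMismatchError):
            append_slow5(blow5_file, [], header=RunHeader())


class TestIndex:
    def test_empty_file_empty_index(self, tmp_path, model):
        path = tmp_path / "e.blow5"
        write_slow5(path, default_header(model), [], binary=True)
        assert len(build_index(path)) == 0

    def test_index_matches_sequential_scan(self, blow5_file, reads20):
        idx = build_index(blow5_file)
        seq = {r.read_id: r for r in stream_reads(blow5_file)}
        assert set(idx.entries) == set(seq)
        offsets = sorted(idx.entries.values())
        for (o1, l1), (o2, _) in zip(offsets, offsets[1:]):
            assert o1 + l1 <= o2  # strictly increasing, no overlap
        for rid in idx.entries:
            assert get_read(blow5_file, idx, rid) == seq[rid]

    def test_get_read_unknown_id(self, blow5_file):
        idx = build_index(blow5_file)
        with pytest.raises(ReadNotFoundError):
            get_read(blow5_file, idx, "missing")

    def test_get_read_stateless(self, blow5_file):
        idx = build_index(blow5_file)
        rid = next(iter(idx.entries))
        assert get_read(blow5_file, idx, rid) == get_read(blow5_file, idx, rid)

    def test_sidecar_reload_without_rescan(self, blow5_file):
        built = build_index(blow5_file, save=True)
        loaded = load_index(blow5_file)
        assert loaded.entries == built.entries

    def test_missing_and_stale_index_detected(self, tmp_path, blow5_file, model):
        with pytest.raises(MissingIndexError):
            load_index(blow5_file)
        build_index(blow5_file, save=True)
        load_index(blow5_file)
        extra = generate_reads(1, 30, MockModel(seed=9), id_prefix="extra", id_start=0)
        append_slow5(blow5_file, reads_only(extra))
        with pytest.raises(StaleIndexError):
            load_index(blow5_file)
        assert len(ensure_index(blow5_file)) == 21  # transparently rebuilt

    def test_truncated_trailing_record_reports_offset(self, tmp_path, blow5_file):
        data = open(blow5_file, "rb").read()
        bad = tmp_path / "trunc.blow5"
        bad.write_bytes(data[:-10])
        with pytest.raises(Slow5ParseError, match="offset"):
            build_index(bad, save=False)

    def test_ascii_is_sequential_only(self, slow5_file):
        with pytest.raises(Exception, match="binary"):
            build_index(slow5_file)
        with Slow5File(slow5_file) as fh:
            with pytest.raises(Exception, match="binary"):
                fh.get_read("sim_000000")
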