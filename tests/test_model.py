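import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slow5pipe.model import (
    CalibrationError,
    PipelineConfig,
    RunHeader,
    SignalRead,
    ValidationError,
    to_pA,
)


def make_read(raw, digitisation=1000.0, offset=0.0, rng=1000.0, **kw):
    defaults = dict(
        read_id="r1", read_group=0, digitisation=digitisation, offset=offset,
        range=rng, sampling_rate=4000.0, raw_signal=np.asarray(raw),
    )
    defaults.update(kw)
    return SignalRead(**defaults)


class TestToPA:
    @pytest.mark.parametrize(
        "raw,offset,rng,dig,expected",
        [
            ([0, 0], 0.0, 1000.0, 1000.0, [0.0, 0.0]),
            ([100], 10.0, 1200.0, 600.0, [220.0]),
            ([-5], 5.0, 100.0, 100.0, [0.0]),
        ],
    )
    def test_calibration_formula(self, raw, offset, rng, dig, expected):
        read = make_read(raw, digitisation=dig, offset=offset, rng=rng)
        assert to_pA(read) == pytest.approx(expected)

    def test_non_positive_digitisation_rejected(self):
        with pytest.raises(CalibrationError):
            make_read([1], digitisation=0.0)
        with pytest.raises(CalibrationError):
            make_read([1], digitisation=-5.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.integers(-32768, 32767), min_size=1, max_size=50),
        b=st.lists(st.integers(-32768, 32767), min_size=1, max_size=50),
        dig=st.floats(1.0, 1e5),
        rng=st.floats(1.0, 1e4),
        offset=st.floats(-100.0, 100.0),
    )
    def test_affine_in_raw_signal(self, a, b, dig, rng, offset):
        """to_pA(a) - to_pA(b) == (a - b) * range/digitisation elementwise."""
        n = min(len(a), len(b))
        ra = make_read(a[:n], digitisation=dig, offset=offset, rng=rng)
        rb = make_read(b[:n], digitisation=dig, offset=offset, rng=rng)
        lhs = to_pA(ra) - to_pA(rb)
        rhs = (np.array(a[:n], dtype=float) - np.array(b[:n], dtype=float)) * (rng / dig)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-9)


class TestSignalReadInvariants:
    def test_read_id_whitespace_rejected(self):
        for bad in ("", "a b", "a\tb", "a\n"):
            with pytest.raises(ValidationError):
                make_read([1], read_id=bad)

    def test_out_of_range_samples_rejected(self):
        with pytest.raises(ValidationError):
            make_read(np.array([40000], dtype=np.int64))

    def test_signal_coerced_to_int16(self):
        read = make_read([1, -2, 3])
        assert read.raw_signal.dtype == np.int16
        assert len(read) == 3


class TestRunHeader:
    def test_attribute_maps_padded_per_group(self):
        h = RunHeader(num_read_groups=3, attributes=({"k": "v"},))
        assert len(h.attributes) == 3
        assert h.attributes[0] == {"k": "v"} and h.attributes[2] == {}

    def test_zero_read_groups_rejected(self):
        with pytest.raises(ValidationError):
            RunHeader(num_read_groups=0)

    def test_duplicate_or_tabbed_aux_names_rejected(self):
        with pytest.raises(ValidationError):
            RunHeader(aux_schema=(("x", "int"), ("x", "float")))
        with pytest.raises(ValidationError):
            RunHeader(aux_schema=(("a\tb", "int"),))

    def test_unknown_codecs_rejected(self):
        with pytest.raises(ValidationError):
            RunHeader(record_codec="lz4")
        with pytest.raises(ValidationError):
            RunHeader(signal_codec="vbz")


class TestPipelineConfig:
    def test_batchsize_bounded_by_queue(self):
        with pytest.raises(ValidationError):
            PipelineConfig(guppy_batchsize=100, max_queued_reads=50)
        cfg = PipelineConfig(guppy_batchsize=50, max_queued_reads=50)
        assert cfg.guppy_batchsize == 50

    def test_positive_integers_required(self):
        with pytest.raises(ValidationError):
            PipelineConfig(procs=0)
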