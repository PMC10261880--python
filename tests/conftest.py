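import numpy as np
import pytest

from slow5pipe import MockModel, default_header, generate_reads, write_slow5


@pytest.fixture(scope="session")
def model():
    return MockModel(seed=1234)


@pytest.fixture(scope="session")
def quiet_model():
    """Noiseless variant of the session model (same calibration/seed)."""
    return MockModel(noise_sd=0.0, seed=1234)


@pytest.fixture(scope="session")
def reads20(model):
    """20 synthetic reads with ground truth, mixed lengths."""
    return generate_reads(20, (30, 120), model)


@pytest.fixture()
def blow5_file(tmp_path, model, reads20):
    path = tmp_path / "reads.blow5"
    write_slow5(path, default_header(model), [r for r, _ in reads20], binary=True)
    return str(path)


@pytest.fixture()
def slow5_file(tmp_path, model, reads20):
    path = tmp_path / "reads.slow5"
    write_slow5(path, default_header(model), [r for r, _ in reads20], binary=False)
    return str(path)


def signals_equal(a, b):
    return a.read_id == b.read_id and np.array_equal(a.raw_signal, b.raw_signal)
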