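import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from frcurve import BenchmarkConfig, LibraryProfile, LibraryRole, run_benchmark

BENCH_SEED = 7  # matches the documented `simulate --seed 7` example


@pytest.fixture(scope="session")
def pe_lib():
    return LibraryProfile(LibraryRole.PE, 300.0, 30.0)


@pytest.fixture(scope="session")
def mp_lib():
    return LibraryProfile(LibraryRole.MP, 3000.0, 300.0)


@pytest.fixture(scope="session")
def std_report():
    """Standard corrupted benchmark: 100 kb genome, PE 80x + MP 20x,
    six typed mis-assembly events."""
    return run_benchmark(BenchmarkConfig(), seed=BENCH_SEED)


@pytest.fixture(scope="session")
def clean_report():
    """Event-free control with the same genome and read model."""
    return run_benchmark(BenchmarkConfig(events=()), seed=BENCH_SEED)
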