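import pytest


@pytest.fixture(scope="session")
def desk_benchmark():
    """One full desk-scale run shared by the end-to-end tests: generate the
    synthetic screen, pre-train both encoders, evaluate every protocol."""
    from cellmol.workflows import BenchmarkConfig, run_benchmark

    return run_benchmark(BenchmarkConfig(seed=1))
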