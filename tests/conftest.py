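import pytest

from sbpred import BenchmarkSpec, PeptideSet, SVMConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A quick separable motif benchmark: 60 positives vs 240 negatives."""
    spec = BenchmarkSpec(n_pos=60, n_neg=240, seed=42)
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def small_pair(small_benchmark):
    """A balanced 60/60 pair from the small benchmark."""
    pos, neg = small_benchmark
    return pos, PeptideSet(neg.peptides[:60], label="negative")


@pytest.fixture(scope="session")
def separable_pair():
    """A cleanly separable 60/60 pair: every positive carries the motif."""
    spec = BenchmarkSpec(n_pos=60, n_neg=60, motif_rate=1.0, seed=13)
    pos, neg = generate_benchmark(spec)
    return pos, neg


@pytest.fixture(scope="session")
def fast_config():
    return SVMConfig.fast()
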