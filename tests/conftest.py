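import numpy as np
import pytest

from mflearn import SyntheticSpec, make_benchmark, make_descriptor


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: 700 molecules, 4 fidelities, sorted-CM features."""
    spec = SyntheticSpec(n_molecules=700, seed=0)
    ds = make_benchmark(spec)
    X = make_descriptor("sorted_cm").fit(ds.molecules).transform(ds.molecules)
    test_idx = np.random.default_rng(123).permutation(ds.n_molecules)[:100]
    return {"spec": spec, "ds": ds, "X": X, "test_idx": test_idx}


@pytest.fixture(scope="session")
def equal_label_benchmark():
    """Benchmark in which every fidelity carries identical labels (no gaps, no noise)."""
    spec = SyntheticSpec(n_molecules=150, difference_scales=(0.0, 0.0, 0.0),
                         noise_sd=0.0, seed=5)
    ds = make_benchmark(spec)
    X = make_descriptor("sorted_cm").fit(ds.molecules).transform(ds.molecules)
    return {"spec": spec, "ds": ds, "X": X, "test_idx": np.arange(130, 150)}


@pytest.fixture(scope="session")
def noisy_benchmark_small():
    """Small noisy benchmark for identity / equivalence checks."""
    spec = SyntheticSpec(n_molecules=200, seed=3)
    ds = make_benchmark(spec)
    X = make_descriptor("sorted_cm").fit(ds.molecules).transform(ds.molecules)
    return {"spec": spec, "ds": ds, "X": X, "test_idx": np.arange(170, 200)}
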