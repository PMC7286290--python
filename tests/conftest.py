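"""Shared fixtures.

The heavy end-to-end artifacts (the default 4-class morphology benchmark,
the classifiers trained on it, and the full control-population pipeline
run) are session-scoped so the acceptance tests share one computation.
"""

import numpy as np
import pytest

ACCEPT_SEED = 20260925


@pytest.fixture(scope="session")
def benchmark_and_classifiers():
    from spimscreen.benchmark import default_benchmark, train_benchmark_classifiers

    bench = default_benchmark(n_per_class=800, seed=ACCEPT_SEED)
    cnn, rf = train_benchmark_classifiers(bench, seed=ACCEPT_SEED)
    return bench, cnn, rf


@pytest.fixture(scope="session")
def control_run(benchmark_and_classifiers):
    from spimscreen.benchmark import control_population_run

    _, cnn, _ = benchmark_and_classifiers
    return control_population_run(cnn, n_cells=64, n_frames=150, seed=ACCEPT_SEED)
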