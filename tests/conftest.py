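import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgfuse as ef
from ecgfuse.features import feature_matrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark50():
    """Balanced synthetic benchmark: 50 beats per class, fixed seed."""
    beats, labels = ef.make_benchmark_dataset(50, rng_seed=0)
    return beats, labels


@pytest.fixture(scope="session")
def benchmark_features(benchmark50):
    beats, _ = benchmark50
    return feature_matrix(beats)


@pytest.fixture(scope="session")
def benchmark_split(benchmark50, benchmark_features):
    """Deterministic 200/50 train/test split of the benchmark."""
    beats, labels = benchmark50
    X = np.vstack([b.samples for b in beats])
    F = benchmark_features
    return {
        "X_train": X[:200], "X_test": X[200:],
        "F_train": F[:200], "F_test": F[200:],
        "y_train": labels[:200], "y_test": labels[200:],
    }


@pytest.fixture(scope="session")
def trained_cnn(benchmark_split):
    """CNN trained on the 200-beat training split (30 epochs, seed 0)."""
    return ef.train_cnn(
        benchmark_split["X_train"], benchmark_split["y_train"],
        ef.TrainingConfig(epochs=30, rng_seed=0),
    )


@pytest.fixture(scope="session")
def trained_svr(benchmark_split):
    """SVR ensemble fitted on the 200-beat training split."""
    from ecgfuse.svr import train_svr_ensemble

    return train_svr_ensemble(benchmark_split["F_train"], benchmark_split["y_train"])
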