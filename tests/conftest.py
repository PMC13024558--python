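import numpy as np
import pytest

from gaitpd.backbones import ModelSpec, TrainingConfig, build_model, train_classifier
from gaitpd.synth import CohortConfig, generate_cohort


def make_blobs(rng, n, shift=6.0, token=3, dim=1):
    """Separable two-class fixture in (18, 2) token space: class 1 is shifted
    far along one feature, so Bayes AUC is ~1."""
    X = rng.normal(size=(n, 18, 2))
    y = rng.integers(0, 2, n)
    X[y == 1, token, dim] += shift
    return X, y


@pytest.fixture(scope="session")
def blob_data():
    rng = np.random.default_rng(42)
    return {
        "train": make_blobs(rng, 400),
        "val": make_blobs(rng, 150),
        "test": make_blobs(rng, 600),
    }


@pytest.fixture(scope="session")
def fast_training():
    return TrainingConfig(learning_rate=3e-3, max_epochs=50, patience=10, seed=0)


@pytest.fixture(scope="session")
def trained_backbones(blob_data, fast_training):
    """One small trained model per architecture, on the separable fixture."""
    out = {}
    for arch in ("tcn", "bigru_attn", "fcnn_transformer"):
        model = build_model(ModelSpec(arch=arch, hidden=16, depth=2), seed=0)
        out[arch] = train_classifier(
            model, blob_data["train"], blob_data["val"], fast_training
        )
    return out


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort with the default (severity-affected) effects."""
    config = CohortConfig(n_control=10, n_pd=12, record_seconds=15.0, seed=3)
    signals, table, truths = generate_cohort(config)
    return {"config": config, "signals": signals, "table": table, "truths": truths}
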