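import numpy as np
import pytest

import tilebayes as tb

# Reduced-scale study conditions shared across the suite: 16 px tiles, a
# narrow three-stage trunk, and short epoch budgets keep every training run
# in the seconds range while preserving the full training/inference path.
MODEL4 = tb.ModelConfig(n_classes=4, input_size=16, filters=(8, 16, 32))


@pytest.fixture(scope="session")
def easy_train():
    """Easy (confusability 0) 4-class tile set, 60 per class."""
    return tb.generate_dataset(4, 60, size=16, seed=42)


@pytest.fixture(scope="session")
def easy_test():
    return tb.generate_dataset(4, 25, size=16, seed=4242)


@pytest.fixture(scope="session")
def trained_model(easy_train):
    """A converged classifier on the easy 4-class set (shared, read-only)."""
    model = tb.build_classifier(MODEL4, seed=0)
    tb.train_classifier(model, easy_train, tb.TrainConfig(epochs=20, seed=0))
    return model


@pytest.fixture(scope="session")
def confusable_model():
    """Classifier trained on a set whose classes 2 and 3 heavily overlap."""
    train = tb.generate_dataset(
        4, 60, size=16, confusable_pair=(2, 3), confusability=0.95, seed=7
    )
    test = tb.generate_dataset(
        4, 25, size=16, confusable_pair=(2, 3), confusability=0.95, seed=77
    )
    model = tb.build_classifier(MODEL4, seed=1)
    tb.train_classifier(model, train, tb.TrainConfig(epochs=20, seed=1))
    return model, train, test


def random_posterior(rng, T, M):
    """Row-stochastic T x M matrix (Dirichlet rows)."""
    return tb.PredictivePosterior(samples=rng.dirichlet(np.ones(M), size=T))
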