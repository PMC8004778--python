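import numpy as np
import pytest

import featfuse as ff
from featfuse.synthetic import BankExtractorSpec, FeatureBankConfig


def complementary_bank_config(seed: int = 7) -> FeatureBankConfig:
    """Five synthetic extractors: two informative on complementary class
    boundaries, one redundant family-mate of the first, two pure noise."""
    return FeatureBankConfig(
        n_samples=400,
        n_classes=4,
        seed=seed,
        extractors=(
            BankExtractorSpec("alpha50", family="alpha", dim=12, n_informative=6,
                              class_separation=6.0, separated_classes=(0, 1)),
            BankExtractorSpec("alpha101", family="alpha", dim=12, n_informative=6,
                              class_separation=5.0, separated_classes=(0, 1)),
            BankExtractorSpec("beta50", family="beta", dim=12, n_informative=6,
                              class_separation=6.0, separated_classes=(2, 3)),
            BankExtractorSpec("gamma1", family="gamma", dim=12, n_informative=4,
                              class_separation=0.0),
            BankExtractorSpec("delta1", family="delta", dim=12, n_informative=4,
                              class_separation=0.0),
        ),
    )


@pytest.fixture(scope="session")
def complementary_results() -> ff.FeatureEnsembleResults:
    """One full experiment on the complementary bank, shared across tests."""
    tables = ff.generate_feature_bank(complementary_bank_config())
    return ff.run_experiment(tables, seed=11, stratified=True)


@pytest.fixture()
def asymmetric_image() -> np.ndarray:
    """A 3x3 image with no dihedral symmetry."""
    return np.arange(9, dtype=float).reshape(3, 3)


@pytest.fixture()
def blob_dataset():
    """Two well-separated 2-D Gaussian blobs, linearly separable."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(loc=(-4.0, -4.0), scale=0.5, size=(50, 2))
    X1 = rng.normal(loc=(4.0, 4.0), scale=0.5, size=(50, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 50 + [1] * 50)
    # hard-margin check: classes on opposite sides of x + y = 0
    assert (X0.sum(axis=1) < -2).all() and (X1.sum(axis=1) > 2).all()
    return X, y
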