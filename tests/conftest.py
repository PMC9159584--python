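import numpy as np
import pytest

from tisscan import (
    SyntheticSpec,
    default_logo,
    generate_labeled_dataset,
    prepare_training_sets,
    train_forest,
)
from tisscan.forest import ATG_SCHEMA, NEAR_COGNATE_SCHEMA


@pytest.fixture(scope="session")
def logo():
    return default_logo()


@pytest.fixture(scope="session")
def atg_split():
    examples = generate_labeled_dataset(SyntheticSpec(n_pos=600, n_neg=900, seed=101))
    pos = [e for e in examples if e.label == 1]
    neg = [e for e in examples if e.label == 0]
    return prepare_training_sets(pos, neg, rng_seed=101)


@pytest.fixture(scope="session")
def atg_model(atg_split):
    return train_forest(
        atg_split.train_pos, atg_split.train_neg, ATG_SCHEMA, n_trees=200, rng_seed=101
    )


@pytest.fixture(scope="session")
def nc_model():
    examples = generate_labeled_dataset(
        SyntheticSpec(n_pos=600, n_neg=900, codon_class="near-cognate", seed=202)
    )
    pos = [e for e in examples if e.label == 1]
    neg = [e for e in examples if e.label == 0]
    split = prepare_training_sets(pos, neg, rng_seed=202)
    return train_forest(
        split.train_pos, split.train_neg, NEAR_COGNATE_SCHEMA, n_trees=200, rng_seed=202
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
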