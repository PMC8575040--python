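import numpy as np
import pytest

from pepstruct import featurize as fz
from pepstruct import model as md
from pepstruct import synthetic as sy


@pytest.fixture(scope="session")
def property_matrix():
    return fz.reduce_property_scales(sy.synthetic_property_scales(seed=0))


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-mer alpha helix, no glycine."""
    return sy.make_ideal_peptide("ACDEFHIKLMNQ", sy.MotifSpec("helix"), seed=1, record_id="helix12")


@pytest.fixture(scope="session")
def strand10():
    """Ideal 10-mer extended strand, no glycine."""
    return sy.make_ideal_peptide("ACDEFHIKLM", sy.MotifSpec("strand"), seed=1, record_id="strand10")


@pytest.fixture(scope="session")
def mixed16():
    """16-mer with helical, coil and strand segments."""
    return sy.make_ideal_peptide(
        "ACDEFHIKLMNQRSTV",
        sy.MotifSpec("mixed", pattern="HHHHHHCCSSSSSSSS"),
        seed=2,
        record_id="mixed16",
    )


TINY_HP = md.NetworkHyperparams(
    embed_dim=6, conv_filters=8, conv_window=3, n_res_blocks=1,
    dense_units=32, dropout_rate=0.1, batch_size=16,
)

SMOKE_HP = md.NetworkHyperparams(
    conv_filters=32, n_res_blocks=1, dense_units=128, dropout_rate=0.1,
)


@pytest.fixture(scope="session")
def tiny_corpus():
    return [(rec, ens) for rec, _, ens in sy.make_training_corpus(12, length_range=(5, 10), seed=7)]


@pytest.fixture(scope="session")
def tiny_bundle(property_matrix, tiny_corpus):
    """A fast 2-fold bundle for interface-level tests (not fit quality)."""
    bundle, _ = md.train_cv(tiny_corpus, property_matrix, TINY_HP, folds=2, seed=11, epochs=2)
    return bundle


@pytest.fixture(scope="session")
def smoke_training(property_matrix):
    """Smoke-scale training: 200 synthetic peptides, 30 epochs, 2 folds.

    Session-scoped because it is the most expensive fixture; both the
    training-progress and the prediction-quality checks consume it.
    """
    corpus = [(rec, ens) for rec, _, ens in sy.make_training_corpus(200, length_range=(5, 20), seed=42)]
    bundle, history = md.train_cv(corpus, property_matrix, SMOKE_HP, folds=2, seed=42, epochs=30)
    return corpus, bundle, history
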