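import hypothesis
import numpy as np
import pytest

from itess import (
    build_background,
    fit_markov,
    generate_organism,
    preset,
)
from itess.synthetic_data import SourceSpec, SynthConfig

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("suite")


def small_config(divergence: float, seed: int, organism: str = "SMALL") -> SynthConfig:
    """A reduced organism for fast unit tests (classes 12/36, short genes)."""
    base = preset("separable")
    pos = SourceSpec(
        transition_matrix=base.pos_source.transition_matrix,
        initial_dist=base.pos_source.initial_dist,
        length_dist=(150, 400),
    )
    alt = SourceSpec(
        transition_matrix=base.neg_source.transition_matrix,
        initial_dist=base.neg_source.initial_dist,
        length_dist=(150, 400),
    )
    return SynthConfig(
        n_essential=12, n_non_essential=36, pos_source=pos, neg_source=alt,
        divergence=divergence, genome_length=5000, seed=seed, organism=organism,
    )


@pytest.fixture(scope="session")
def small_separable():
    dataset, genome = generate_organism(small_config(1.0, seed=11))
    return dataset


@pytest.fixture(scope="session")
def small_null():
    dataset, genome = generate_organism(small_config(0.0, seed=12))
    return dataset


@pytest.fixture(scope="session")
def small_background(small_separable):
    return build_background(small_separable.organism, genome=small_separable.genome)


@pytest.fixture(scope="session")
def small_chains(small_separable):
    pos = [g.sequence for g in small_separable.genes if g.label == "essential"]
    neg = [g.sequence for g in small_separable.genes if g.label == "non_essential"]
    return (
        fit_markov(pos, 1, class_tag="positive"),
        fit_markov(neg, 1, class_tag="negative"),
    )


@pytest.fixture(scope="session")
def small_vectors(small_separable, small_background, small_chains):
    from itess import extract_features

    pos_chain, neg_chain = small_chains
    pos = [g.sequence for g in small_separable.genes if g.label == "essential"]
    neg = [g.sequence for g in small_separable.genes if g.label == "non_essential"]
    return extract_features(
        small_separable, small_background, pos_chain, neg_chain,
        train_pos=pos, train_neg=neg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
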