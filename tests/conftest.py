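import pytest

from ipscmut import (
    GeneratorConfig,
    PassagingModel,
    exact_distribution,
    generate_mutation_set,
    generate_reference,
    uv_signature,
)


@pytest.fixture(scope="session")
def uv_reference_and_set():
    """A 200-kb synthetic reference plus 1000 UV-signature SNVs and 50
    indels — shared by the recovery and conservation tests."""
    config = GeneratorConfig(
        seq_length=200_000, n_snv=1000, n_indel=50,
        signature=uv_signature(0.9), seed=7,
    )
    reference = generate_reference(config)
    mutations = generate_mutation_set(reference, config)
    return reference, mutations, config


@pytest.fixture(scope="session")
def study_model():
    """The study's dish: 140 colonies, 20 founder clones, pick 20, split 7."""
    return PassagingModel(n_colonies=140, n_clones0=20, n_picked=20, split_factor=7)


@pytest.fixture(scope="session")
def study_exact_distribution(study_model):
    """Exact clone-count law for 20 passages (computed once; ~10 s)."""
    return exact_distribution(study_model, 20)
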