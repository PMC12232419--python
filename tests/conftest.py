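import pytest
from hypothesis import settings

from herbnet.synthetic import default_study_spec, generate_knowledge_base

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """Canonical planted study: one 4-herb rule at confidence 0.8, seed 1."""
    spec = default_study_spec(seed=1)
    kb, truth, g = generate_knowledge_base(spec)
    return spec, kb, truth, g


@pytest.fixture
def toy_kb():
    from herbnet.knowledge_base import KnowledgeBase

    return KnowledgeBase(
        prescriptions={
            "rx1": frozenset({"hA", "hB"}),
            "rx2": frozenset({"hA", "hC"}),
            "rx3": frozenset({"hB"}),
        },
        indications={"rx1": frozenset({"ph1"}), "rx2": frozenset({"ph1", "ph2"})},
        herb_compounds={
            "hA": frozenset({"c1", "c2"}),
            "hB": frozenset({"c2", "c3"}),
            "hC": frozenset({"c4"}),
        },
        compound_targets={
            "c1": frozenset({"g1", "g2"}),
            "c2": frozenset({"g2", "g3"}),
            "c3": frozenset({"g4"}),
        },
        phenotype_genes={"ph1": frozenset({"g1", "g4"}), "ph2": frozenset({"g2"})},
    )
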