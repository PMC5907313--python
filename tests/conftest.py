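import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from liversim import (
    BranchPoint,
    FluxSource,
    ModelDocument,
    Reaction,
    ReceptorPair,
    Species,
    build_reference_document,
    compile_model,
)


def make_chain_doc():
    """source(1) -> A -> B -> sink."""
    return ModelDocument(
        species=[
            Species(id="A", compartment="liver"),
            Species(id="B", compartment="liver"),
            Species(id="sink", compartment="blood", is_boundary=True),
        ],
        reactions=[
            Reaction(id="r1", substrates=[("A", 1)], products=[("B", 1)]),
            Reaction(id="r2", substrates=[("B", 1)], products=[("sink", 1)]),
        ],
        flux_sources=[FluxSource(id="feed", target_species="A", basal_rate=1.0)],
    )


def make_branch_doc(f=(0.5, 0.5)):
    """source(1) -> A; A splits to B and C; B, C -> sinks."""
    return ModelDocument(
        species=[
            Species(id="A", compartment="liver"),
            Species(id="B", compartment="liver"),
            Species(id="C", compartment="liver"),
            Species(id="sink", compartment="blood", is_boundary=True),
        ],
        reactions=[
            Reaction(id="rB", substrates=[("A", 1)], products=[("B", 1)]),
            Reaction(id="rC", substrates=[("A", 1)], products=[("C", 1)]),
            Reaction(id="dB", substrates=[("B", 1)], products=[("sink", 1)]),
            Reaction(id="dC", substrates=[("C", 1)], products=[("sink", 1)]),
        ],
        branch_points=[
            BranchPoint(id="bp", source_species="A",
                        fractions={"rB": f[0], "rC": f[1]})
        ],
        flux_sources=[FluxSource(id="feed", target_species="A", basal_rate=1.0)],
    )


def make_hormone_doc():
    """Minimal document with the full hormonal layer, diet sources, one branch
    and one unregulated mrna species."""
    species = [
        Species(id="growth_hormone", compartment="blood", role="hormone"),
        Species(id="androgen", compartment="blood", role="hormone"),
        Species(id="estrogen", compartment="blood", role="hormone"),
        Species(id="GHR_inactive", compartment="liver", role="receptor_inactive"),
        Species(id="GHR_active", compartment="liver", role="receptor_active"),
        Species(id="AR_inactive", compartment="liver", role="receptor_inactive"),
        Species(id="AR_active", compartment="liver", role="receptor_active"),
        Species(id="ER_inactive", compartment="liver", role="receptor_inactive"),
        Species(id="ER_active", compartment="liver", role="receptor_active"),
        Species(id="Lipid", compartment="liver"),
        Species(id="LipidA", compartment="adipose"),
        Species(id="LipidB", compartment="blood"),
        Species(id="Sterol", compartment="liver"),
        Species(id="Sugar", compartment="blood"),
        Species(id="GeneX", compartment="liver", role="mrna"),
    ]
    reactions = [
        Reaction(id="r_gh_clear", substrates=[("growth_hormone", 1)], products=[]),
        Reaction(id="r_an_clear", substrates=[("androgen", 1)], products=[]),
        Reaction(id="r_es_clear", substrates=[("estrogen", 1)], products=[]),
        Reaction(id="rA", substrates=[("Lipid", 1)], products=[("LipidA", 1)]),
        Reaction(id="rB", substrates=[("Lipid", 1)], products=[("LipidB", 1)]),
        Reaction(id="dA", substrates=[("LipidA", 1)], products=[]),
        Reaction(id="dB", substrates=[("LipidB", 1)], products=[]),
        Reaction(id="d_sterol", substrates=[("Sterol", 1)], products=[]),
        Reaction(id="d_sugar", substrates=[("Sugar", 1)], products=[]),
        Reaction(id="d_genex", substrates=[("GeneX", 1)], products=[]),
    ]
    sources = [
        FluxSource(id="growth_hormone_source", target_species="growth_hormone"),
        FluxSource(id="androgen_source", target_species="androgen"),
        FluxSource(id="estrogen_source", target_species="estrogen"),
        FluxSource(id="triglyceride", target_species="Lipid", basal_rate=1.0),
        FluxSource(id="cholesterol", target_species="Sterol", basal_rate=1.0),
        FluxSource(id="glucose", target_species="Sugar", basal_rate=1.0),
        FluxSource(id="syn_GeneX", target_species="GeneX", basal_rate=0.5),
    ]
    pairs = [
        ReceptorPair(hormone="growth_hormone", inactive_species="GHR_inactive",
                     active_species="GHR_active"),
        ReceptorPair(hormone="androgen", inactive_species="AR_inactive",
                     active_species="AR_active"),
        ReceptorPair(hormone="estrogen", inactive_species="ER_inactive",
                     active_species="ER_active"),
    ]
    return ModelDocument(
        species=species,
        reactions=reactions,
        branch_points=[
            BranchPoint(id="bp", source_species="Lipid",
                        fractions={"rA": 0.5, "rB": 0.5})
        ],
        flux_sources=sources,
        receptor_pairs=pairs,
    )


@pytest.fixture
def chain_doc():
    return make_chain_doc()


@pytest.fixture
def branch_doc():
    return make_branch_doc()


@pytest.fixture
def hormone_doc():
    return make_hormone_doc()


@pytest.fixture(scope="session")
def reference_doc():
    return build_reference_document()


@pytest.fixture
def chain_model(chain_doc):
    return compile_model(chain_doc)
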