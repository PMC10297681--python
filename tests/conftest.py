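import pytest

from voicechain import (
    EnsembleSpec,
    Pathway,
    PathwayEnsemble,
    TerminalSet,
    build_cohort,
    generate_ensemble,
)
from voicechain.fixtures import load_acc_ensemble, load_table1


@pytest.fixture(scope="session")
def acc_ensemble():
    """The packaged single-pathway ACC ensemble."""
    return load_acc_ensemble()


@pytest.fixture(scope="session")
def table1_records():
    """All 76 syndrome rows of the packaged table transcription."""
    return load_table1()


@pytest.fixture(scope="session")
def cohort(table1_records):
    """The merged, analyzable 73-syndrome cohort."""
    return build_cohort(table1_records)


def make_ensemble(*gene_sets: set[str]) -> PathwayEnsemble:
    """Tiny hand-built ensemble; pathways are named B0, B1, ..."""
    return PathwayEnsemble.from_pathways(
        Pathway(id=f"B{i}", name=f"B{i}", genes=frozenset(gs))
        for i, gs in enumerate(gene_sets)
    )


@pytest.fixture()
def two_hop_ensemble():
    """B0 = head pathway {FOXP2, g2}; B1 = {g2, g3} linked through g2."""
    return make_ensemble({"FOXP2", "G2"}, {"G2", "G3"})


@pytest.fixture(scope="session")
def dense_ensemble():
    """A 20-pathway synthetic ensemble dense enough to contain all gene classes."""
    return generate_ensemble(EnsembleSpec(
        n_pathways=20, gene_universe_size=400, overlap_density=0.3, seed=5))


@pytest.fixture()
def region(request):
    def _make(genes, name="region"):
        return TerminalSet(name=name, genes=frozenset(genes))
    return _make
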