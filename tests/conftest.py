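import pytest

from biodocsim.mesh_ontology import MeshForest, MeshHeading, compute_ic
from biodocsim.pipeline import PipelineConfig, run_pipeline
from biodocsim.synthetic_data import (
    SyntheticSpec,
    generate_corpus,
    generate_embeddings,
    generate_mesh_forest,
)

# The Melanosomes / Sarcomeres tree numbers of the real MeSH vocabulary,
# used for hand-derived depth/LCA/path values.
MELANOSOMES_NODES = frozenset(
    {
        "A11.284.430.214.190.500.560",
        "A11.284.430.214.190.875.190.190.560",
        "A11.409.750.560",
        "A11.436.265.531.560",
        "A11.436.613.560",
    }
)
SARCOMERES_NODES = frozenset(
    {
        "A10.690.552.875.700",
        "A11.284.430.214.190.875.820",
        "A11.620.249.850.700",
        "A11.620.500.500.700",
    }
)


@pytest.fixture(scope="session")
def real_heading_forest() -> MeshForest:
    return MeshForest.from_headings(
        [
            MeshHeading("Melanosomes", MELANOSOMES_NODES),
            MeshHeading("Sarcomeres", SARCOMERES_NODES),
        ]
    )


@pytest.fixture(scope="session")
def toy_forest() -> MeshForest:
    """Two small subtrees (<= 25 nodes incl. implicit ancestors) with counts
    chosen so every IC value is a simple closed form."""
    forest = MeshForest.from_headings(
        [
            MeshHeading("Root", frozenset({"A01"})),
            MeshHeading("ChildA", frozenset({"A01.100"})),
            MeshHeading("ChildB", frozenset({"A01.200"})),
            MeshHeading("GrandA1", frozenset({"A01.100.110"})),
            MeshHeading("GrandA2", frozenset({"A01.100.120"})),
            MeshHeading("DeepA", frozenset({"A01.100.110.115"})),
            MeshHeading("OtherTree", frozenset({"B01"})),
            MeshHeading("OtherChild", frozenset({"B01.500"})),
            MeshHeading("Bridging", frozenset({"A01.200.210", "B01.500.510"})),
        ]
    )
    for node in forest.nodes:
        forest.counts[node] = 2.0
    compute_ic(forest, smoothing=1.0)
    return forest


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def synthetic_bundle(default_spec):
    """Default synthetic study corpus: forest, embeddings, corpus, relevance."""
    forest = generate_mesh_forest(default_spec)
    embeddings = generate_embeddings(default_spec)
    corpus, relevance = generate_corpus(default_spec, forest, embeddings)
    return forest, embeddings, corpus, relevance


@pytest.fixture(scope="session")
def small_bundle():
    """A cheap 3-topic corpus for fast integration tests."""
    spec = SyntheticSpec(n_topics=3, docs_per_topic=12, seed=1)
    forest = generate_mesh_forest(spec)
    embeddings = generate_embeddings(spec)
    corpus, relevance = generate_corpus(spec, forest, embeddings)
    return spec, forest, embeddings, corpus, relevance


@pytest.fixture(scope="session")
def pipeline_result(synthetic_bundle):
    forest, embeddings, corpus, relevance = synthetic_bundle
    return run_pipeline(corpus, relevance, forest, embeddings, PipelineConfig())
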