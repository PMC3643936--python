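import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from modulenet.pipeline import RunConfig, run_all
from modulenet.subgraphs import Subgraph
from modulenet.synthdata import PlantedDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_subgraph(genes, layer="ppi", sid=None, graph=None):
    """A Subgraph over the given genes; a path graph keeps it connected."""
    genes = sorted(genes)
    if graph is None:
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        for a, b in zip(genes, genes[1:]):
            graph.add_edge(a, b, weight=1.0)
    return Subgraph(
        id=sid or f"{layer}:{'|'.join(genes[:3])}:{len(genes)}",
        source_layer=layer,
        genes=frozenset(genes),
        graph=graph,
    )


@pytest.fixture(scope="session")
def small_design():
    """A miniature benchmark for fast pipeline-level tests."""
    return PlantedDesign(
        n_genes=80, n_modules=3, module_size=8,
        shared_modules=(0, 1),
        layer_private={"ppi": (2,), "genetic": ()},
        coreg_modules=(0, 1), bridge=False,
        n_treatments=20,
        background_term_sizes=(4,) * 20 + (5,) * 10,
        markers_per_module=2,
    )


@pytest.fixture(scope="session")
def bench_run(tmp_path_factory):
    """One full default-benchmark analysis, shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    config = RunConfig(outdir=str(out))
    result = run_all(config)
    return result


@pytest.fixture(scope="session")
def bench_bundle_dir(bench_run):
    return bench_run.config.outdir
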