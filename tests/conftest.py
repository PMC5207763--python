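import pytest

from genecycle.phylo import (
    LineageConfig,
    parse_newick,
    resolve_lineage,
)
from genecycle.pipeline import RunConfig, run_pipeline
from genecycle.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def toy_tree():
    """(((F,A),B),(C,D)) with unit-ish lengths; focal F, outgroup {B,C,D}."""
    return parse_newick("(((F:1,A:1)X:1,B:2)Y:1,(C:1,D:1)Z:2)R;", focal="F")


@pytest.fixture(scope="session")
def toy_lineage(toy_tree):
    # threshold at Y: lineages splitting from the focal path below Y are "local"
    return resolve_lineage(toy_tree, LineageConfig(focal="F", local_threshold="Y"))


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but fully featured synthetic bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=11, n_species=14, n_genes=1600, n_conditions=60)
    return simulate_bundle(cfg, outdir)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(indir=small_bundle["outdir"], outdir=outdir, seed=3)
    return cfg, run_pipeline(cfg)
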