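import pytest

from lstscreen.pipeline import run_screen
from lstscreen.simulate import SimulationConfig, build_synthetic_taxonomy, simulate
from lstscreen.taxonomy import GroupConfig


@pytest.fixture(scope="session")
def synthetic_taxonomy():
    """(tree, species-per-origin-class, self taxid) — deterministic."""
    return build_synthetic_taxonomy()


@pytest.fixture(scope="session")
def tree(synthetic_taxonomy):
    return synthetic_taxonomy[0]


@pytest.fixture(scope="session")
def species(synthetic_taxonomy):
    return synthetic_taxonomy[1]


@pytest.fixture(scope="session")
def self_taxid(synthetic_taxonomy):
    return synthetic_taxonomy[2]


@pytest.fixture(scope="session")
def group_config():
    return GroupConfig.default()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Small planted bundle: 60 scaffolds + 3 contaminant scaffolds of 4 genes."""
    config = SimulationConfig(
        seed=11, n_scaffolds=60, n_contaminant_scaffolds=3, contaminant_genes_per_scaffold=4
    )
    return simulate(config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def screen_result(bundle, tmp_path_factory):
    return run_screen(
        bundle.fasta,
        bundle.gff3,
        bundle.hits,
        bundle.counts,
        bundle.node_table,
        bundle.name_table,
        self_taxids=[bundle.self_taxid],
        outdir=tmp_path_factory.mktemp("screen_out"),
    )
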