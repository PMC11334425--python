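import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from flavimine.synthetic import SimConfig, simulate_genomes, write_genome_set

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small fully-planted genome set (every genome has an anchor+target)."""
    cfg = SimConfig(seed=7, n_genomes=12, genes_per_contig=30, p_cluster=1.0)
    genomes, truth = simulate_genomes(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_sim):
    """The same genome set written to disk in the pipeline's input layout."""
    _cfg, genomes, truth = small_sim
    out = tmp_path_factory.mktemp("synthetic")
    write_genome_set(genomes, truth, out)
    return out


@pytest.fixture()
def multi_site_sim():
    """Targets planted with many motif sites (multi-flavinylated regime)."""
    cfg = SimConfig(
        seed=11, n_genomes=4, genes_per_contig=20, p_cluster=1.0,
        n_motif_sites=5, protein_len_range=(300, 500),
    )
    return (cfg, *simulate_genomes(cfg))


@pytest.fixture()
def replace_cfg():
    return dataclasses.replace
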