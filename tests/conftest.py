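import pytest

from ss3x.sim_reads import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Mixed dataset: artifacts, tag mutations, corrupted qualities."""
    cfg = SimConfig(
        n_cells=4, reads_per_cell=600, frac_umi_reads=0.6,
        frac_artifact=0.1, seed=11,
        corrupt_fraction=0.1, frac_tag_mutated=0.1,
    )
    return simulate(cfg, tmp_path_factory.mktemp("sim_small"))


@pytest.fixture(scope="session")
def sim_paired(tmp_path_factory):
    """Paired-end dataset for flag handling and mate-integrity checks."""
    cfg = SimConfig(
        n_cells=3, reads_per_cell=300, frac_umi_reads=0.6,
        frac_artifact=0.15, seed=7, paired=True,
    )
    return simulate(cfg, tmp_path_factory.mktemp("sim_paired"))


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """Artifact-free, corruption-free dataset with one molecule per gene."""
    cfg = SimConfig(
        n_cells=6, reads_per_cell=800, frac_umi_reads=0.7,
        frac_artifact=0.0, seed=23, molecules_per_gene=1,
    )
    return simulate(cfg, tmp_path_factory.mktemp("sim_clean"))
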