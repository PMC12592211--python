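import pytest

from uvsdr import pipeline, simulate


@pytest.fixture(scope="session")
def tiny_sim_cfg() -> simulate.SimulationConfig:
    """Small, fast study system: 3 x 200-kb chromosomes, 100-kb SDR."""
    return simulate.SimulationConfig(
        seed=1,
        n_autosomes=2,
        autosome_len=200_000,
        uv_len=200_000,
        sdr_start=50_000,
        sdr_len=100_000,
        n_gametologues=4,
        n_sex_specific=2,
        n_autosomal_genes=16,
        n_par_genes=6,
        depth=12.0,
    )


@pytest.fixture(scope="session")
def tiny_genomes(tiny_sim_cfg):
    return simulate.simulate_genome_pair(tiny_sim_cfg)


@pytest.fixture(scope="session")
def demo_report() -> dict:
    """The full default-scale demonstration run (10-Mb genomes, 15x reads),
    shared across the acceptance checks that exercise it."""
    return pipeline.run_demo(pipeline.PipelineConfig())
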