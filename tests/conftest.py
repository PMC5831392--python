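import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from srnapipe.pipeline import PipelineConfig, run_pipeline
from srnapipe.simulate import SimulationConfig, simulate_all

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def small_sim_config(seed: int = 11, **overrides) -> SimulationConfig:
    params = dict(
        seed=seed,
        n_known_mirnas=12,
        n_novel_loci=4,
        n_genes=120,
        n_reads_per_library=6000,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def dataset():
    """One small synthetic study shared across tests."""
    return simulate_all(small_sim_config())


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """A full end-to-end run on a small synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=str(outdir), seed=11)
    config.simulate = small_sim_config()
    return run_pipeline(config)
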