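import pytest

from rnamend.pipeline import PipelineConfig, run_pipeline
from rnamend.simulate import FixtureConfig, generate_truth_set, simulate_reads


@pytest.fixture(scope="session")
def clean_world():
    """Uncorrupted 6-gene fixture: predictions match the truth exactly."""
    cfg = FixtureConfig(
        seed=11, n_genes=6, n_scaffolds=1, scaffold_len=25000, corruption_rates={}
    )
    truth = generate_truth_set(cfg)
    reads = simulate_reads(truth)
    return truth, reads


@pytest.fixture(scope="session")
def clean_report(clean_world):
    truth, reads = clean_world
    return run_pipeline(truth.genome, truth.corrupted_models, reads, PipelineConfig())


@pytest.fixture(scope="session")
def corrupted_world():
    """The default study conditions: 20 genes, every corruption type, depth 23."""
    cfg = FixtureConfig(seed=1)
    truth = generate_truth_set(cfg)
    reads = simulate_reads(truth)
    return truth, reads


@pytest.fixture(scope="session")
def corrupted_report(corrupted_world):
    truth, reads = corrupted_world
    return run_pipeline(truth.genome, truth.corrupted_models, reads, PipelineConfig())
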