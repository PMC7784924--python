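import numpy as np
import pytest

from aeromyco.pipeline import PipelineConfig, analyse_dataset, run_pipeline
from aeromyco.synth import GeneratorConfig, StudyDesign, simulate_study


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A one-site study at reduced depth: same structure, desk-scale cost."""
    kwargs = dict(seed=seed, mean_depth=2000.0, design=StudyDesign(sites=1))
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_run(small_dataset):
    cfg = PipelineConfig(seed=7, generator=small_dataset.config, min_reads=1000, n_perm=99)
    return analyse_dataset(small_dataset, cfg)


@pytest.fixture(scope="session")
def default_run():
    """The full study at its default conditions (5 sites, mean depth 20k)."""
    cfg = PipelineConfig(seed=11, n_perm=199)
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
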