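import numpy as np
import pytest

from tagdge.synthetic_data import SyntheticConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20130508)


@pytest.fixture(scope="session")
def small_study():
    """A compact three-species study: 200 genes, 120k tags per library."""
    cfg = SyntheticConfig(
        n_genes=200,
        library_depth=120_000,
        divergence=0.02,
        de_fraction=0.15,
        effect_log2=2.0,
        singleton_noise_rate=0.05,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    from tagdge.synthetic_data import write_study

    outdir = tmp_path_factory.mktemp("study")
    write_study(small_study, outdir)
    return outdir
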