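import numpy as np
import pytest

from borealprio.ensemble import (EnsembleConfig, default_bundle, run_baseline,
                                 run_ensemble)
from borealprio.landscape import LandscapeConfig


@pytest.fixture(scope="session")
def small_bundle():
    config = LandscapeConfig(grid_rows=40, grid_cols=40, n_segments=160,
                             master_seed=11)
    return default_bundle(config, seed=11)


@pytest.fixture(scope="session")
def small_baseline(small_bundle):
    return run_baseline(small_bundle, EnsembleConfig(variants=("combined",),
                                                     master_seed=11))


@pytest.fixture(scope="session")
def small_ensemble(small_bundle):
    config = EnsembleConfig(n_iterations=4, variants=("combined",),
                            master_seed=11)
    return run_ensemble(small_bundle, config)
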