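import numpy as np
import pytest

from mmsurv.nn.model import FusionConfig
from mmsurv.synthetic import SimulationConfig, simulate_cohort
from mmsurv.tabular import discretize, to_prompts


@pytest.fixture(scope="session")
def toy_cohort():
    """Small multimodal cohort with missingness, shared across tests."""
    cfg = SimulationConfig(
        n_subjects=80,
        missing_rate={"mgmtp": 0.2, "kps": 0.25, "idh": 0.1},
        seed=11,
    )
    records, truth, volumes = simulate_cohort(cfg)
    prompts = np.array([to_prompts(discretize(r)) for r in records], dtype=object)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "volumes": np.asarray(volumes),
        "prompts": prompts,
    }


@pytest.fixture(scope="session")
def toy_fusion_config():
    return FusionConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
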