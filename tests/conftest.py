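import numpy as np
import pytest

from rivaldec.model import BinocularRivalryDecoder
from rivaldec.paradigm import bnr_design, br_design
from rivaldec.simgen import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def canonical_bnr():
    return bnr_design()


@pytest.fixture(scope="session")
def canonical_br():
    return br_design()


@pytest.fixture(scope="session")
def synthetic_subject():
    """One seeded synthetic subject (localizer + rivalry runs + behavior)."""
    cfg = SimConfig(seed=7)
    bnr, br, log, phases = simulate_subject(cfg)
    return cfg, bnr, br, log, phases


@pytest.fixture(scope="session")
def fitted_decoder(synthetic_subject):
    """The full pipeline run once on the session subject (shared: expensive)."""
    _, bnr, br, log, _ = synthetic_subject
    model = BinocularRivalryDecoder.from_runs(
        bnr.volumes, bnr_design(), br.volumes, br_design(), log, kmeans_seed=7
    )
    results = model.fit(seed=7)
    return model, results


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
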