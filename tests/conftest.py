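import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a synthetic mature miR sequence used wherever a scan query is needed
MIR_SEQ = "UGAUUGGUACGUCUGUGGGUAG"


@pytest.fixture(scope="session")
def mir_seq() -> str:
    return MIR_SEQ


@pytest.fixture(scope="session")
def planted_utr(mir_seq):
    """803-nt synthetic UTR with a 7mer-m8 at 66 and an 8mer-A1 at 759."""
    from mirhts.simulate import plant_utr_sites

    return plant_utr_sites(
        803, mir_seq, [66, 759], ["7mer-m8", "8mer-A1"], rng_seed=11
    )


@pytest.fixture(scope="session")
def planted_screen():
    """Full-size screen with 5 planted inhibitory constructs, fixed seed."""
    from mirhts.simulate import planted_screen_scenario, simulate_screen

    return simulate_screen(planted_screen_scenario(rng_seed=2024))


@pytest.fixture(scope="session")
def small_universe():
    from mirhts.simulate import simulate_prediction_universe

    return simulate_prediction_universe(
        n_genes=400, planted_targets=["TGTA", "TGTB"], rng_seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
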