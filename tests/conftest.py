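import numpy as np
import pytest

from numtkit.simulate import EventSpec, SimulationConfig, implant_numts, simulate_mitogenome


@pytest.fixture(scope="session")
def mito():
    """A deterministic 13-gene synthetic mitogenome shared across tests."""
    return simulate_mitogenome(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome with known implants (events + classes)."""
    cfg = SimulationConfig(
        seed=7,
        chromosomes=[("chr1", 150_000, "autosome"), ("chr2", 120_000, "autosome"),
                     ("chrX", 100_000, "X")],
        events=[
            EventSpec(gene="COX1", lineage="diverged", divergence=0.12,
                      third_multiplier=8.0, copies=2, within_family_divergence=0.01),
            EventSpec(gene="COX1", lineage="contemporary", copies=2),
            EventSpec(gene="ND3", lineage="contemporary", copies=1,
                      target_class="C3"),
            EventSpec(gene="ATP8", lineage="contemporary", copies=3),
        ],
    )
    m = simulate_mitogenome(cfg)
    nuclear, truth, meta = implant_numts(cfg, m)
    return cfg, m, nuclear, truth, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
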