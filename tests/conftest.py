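import pytest

from kinomescreen import SimulationConfig, score_screen, simulate_screen


@pytest.fixture(scope="session")
def small_sim():
    """Small screen (40 genes, 1 plate, 7 samples, duplicate) with truth."""
    cfg = SimulationConfig(n_genes=40, n_differential=6, seed=42)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def default_run():
    """One full default screen with its score table."""
    dataset, truth = simulate_screen(SimulationConfig(seed=11))
    scores = score_screen(dataset)
    return dataset, truth, scores
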