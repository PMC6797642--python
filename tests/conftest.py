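import numpy as np
import pytest

import sparsesca as ss


@pytest.fixture(scope="session")
def herring():
    """Preprocessed two-block herring data (21 x (10 + 10))."""
    return ss.pre_process(ss.load_herring())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_multiblock(I, widths, seed=0, scale=1.0):
    """Small random multiblock dataset, preprocessed."""
    rng = np.random.default_rng(seed)
    blocks = [scale * rng.standard_normal((I, J)) for J in widths]
    raw = ss.MultiblockData(
        blocks=blocks,
        row_ids=[f"s{i}" for i in range(I)],
        block_names=[f"block_{k + 1}" for k in range(len(widths))],
        var_names=[[f"b{k + 1}v{j}" for j in range(J)] for k, J in enumerate(widths)],
    )
    return ss.pre_process(raw)


@pytest.fixture
def small_data():
    return make_multiblock(8, (4, 3), seed=7)


@pytest.fixture
def medium_data():
    return make_multiblock(20, (6, 6), seed=11)


@pytest.fixture(scope="session")
def recovery_sim():
    """Seeded simulation with one common + two distinctive components."""
    status = np.array([[1, 1, 0], [1, 0, 1]])
    design = ss.SimulationDesign(
        I=50,
        J=(12, 10),
        R=3,
        structure=ss.TargetStructure(status),
        noise_proportion=0.05,
        seed=1,
    )
    data, T_true, P_true = ss.simulate_multiblock(design)
    return design, data, T_true, P_true
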