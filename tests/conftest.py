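import numpy as np
import pandas as pd
import pytest

from modflex import ExpressionMatrix, build_network, detect_modules
from modflex.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 400 genes, 3 planted modules, one dissolved causal module."""
    return SimulationConfig(
        n_genes=400,
        module_sizes=(60, 50, 40),
        within_module_cor=0.7,
        dissolved_modules=(0,),
        causal_module=0,
        deg_genes=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_partition(small_study):
    """Modules detected on the intact treated baseline of the small study."""
    x = small_study.samples_for("DHI", "Day0")
    net = build_network(x, 6)
    part = detect_modules(net.tom, expression=x, min_module_size=20)
    return x, net, part


@pytest.fixture()
def noise_matrix():
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        pd.DataFrame(
            rng.standard_normal((50, 30)),
            index=[f"G{i:03d}" for i in range(50)],
            columns=[f"S{i:02d}" for i in range(30)],
        )
    )
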