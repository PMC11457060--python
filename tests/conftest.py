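import numpy as np
import pandas as pd
import pytest

import strigagp as sg


@pytest.fixture(scope="session")
def small_trial():
    """A compact 3-location trial with known variance components."""
    cfg = sg.SimulationConfig(
        n_lines=60, n_markers=120, n_testers=1, block_size=6,
        var_genetic=80.0, var_gxe=23.0, var_error=160.0,
        var_env=40.0, var_replicate=4.0, var_block=4.0, seed=11,
    )
    markers = sg.simulate_markers(cfg)
    plots, truth = sg.simulate_trial(cfg, markers)
    return cfg, markers, plots, truth


@pytest.fixture(scope="session")
def cell_level_dataset():
    """One observation per line x environment, matching the reaction-norm
    model exactly (no replicates, no nuisance design effects)."""

    def make(seed, n_lines=300, n_markers=150):
        cfg = sg.SimulationConfig(
            n_lines=n_lines, n_markers=n_markers, n_testers=1, block_size=5,
            n_replicates=1, var_replicate=0.0, var_block=0.0,
            var_genetic=80.0, var_gxe=23.0, var_error=160.0, var_env=40.0,
            seed=seed,
        )
        markers = sg.simulate_markers(cfg)
        plots, truth = sg.simulate_trial(cfg, markers)
        cells = plots.pivot_table(index="entry", columns="location", values="Y")
        grm = sg.compute_grm(sg.qc_markers(markers))
        return cfg, cells, grm, truth

    return make


@pytest.fixture
def toy_kernel():
    rng = np.random.default_rng(5)
    n = 20
    a = rng.standard_normal((n, 30))
    values = a @ a.T / 30 + 0.3 * np.eye(n)
    ids = [f"L{i}" for i in range(n)]
    return sg.Kernel(values, ids), rng
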