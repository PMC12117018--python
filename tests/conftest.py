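import numpy as np
import pandas as pd
import pytest

from clonetrack import synthetic


@pytest.fixture(scope="session")
def small_experiment():
    """Two models, primary + two secondaries, ground truth attached."""
    cfg = synthetic.ExperimentConfig(
        models=[
            synthetic.XenograftModelConfig(name="M1", n_clones=80),
            synthetic.XenograftModelConfig(name="M2", n_clones=60),
        ]
    )
    return synthetic.simulate_experiment(cfg, seed=42)


@pytest.fixture(scope="session")
def sc_fixture():
    clones = pd.DataFrame(
        {
            "barcode": synthetic.generate_barcode_library(12, seed=7).barcodes,
            "cells": [6000] + [250] * 11,
        }
    )
    return synthetic.simulate_single_cell_fixture(
        clones,
        n_cells=2000,
        doublet_rate=0.04,
        multi_integration_rate=0.15,
        n_metacells=16,
        n_genes=80,
        seed=8,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
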