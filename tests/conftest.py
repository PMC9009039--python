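import numpy as np
import pandas as pd
import pytest

import ifliver as il
from ifliver import preprocess


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset (seed 1), shared across tests."""
    cfg = il.SimConfig(seed=1)
    probe_matrix, probe_map, sheet, truth = il.simulate_dataset(cfg)
    return cfg, probe_matrix, probe_map, sheet, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Summarized expression, model fit, contrasts and filtered set for seed 1."""
    cfg, probe_matrix, probe_map, sheet, truth = default_sim
    expr = preprocess.summarize_probesets(probe_matrix, probe_map)
    fit = il.fit_linear_model(expr, sheet)
    prior = il.estimate_variance_prior(fit)
    table = il.pairwise_contrasts(fit, prior)
    deg = il.filter_de(table)
    return {
        "config": cfg,
        "sheet": sheet,
        "truth": truth,
        "expr": expr,
        "fit": fit,
        "prior": prior,
        "contrasts": table,
        "deg": deg,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sheet():
    """A minimal balanced sample sheet: 2 arrays per treatment."""
    rows = []
    for t in il.TREATMENTS:
        for i in (1, 2):
            rows.append((f"{t}_{i}", t, f"bird_{t}_{i}"))
    return pd.DataFrame(
        rows, columns=["array_id", "treatment", "individual_id"]
    ).set_index("array_id")
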