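import logging

import numpy as np
import pandas as pd
import pytest

from bbbscore import enrichment, io_formats, synthetic_data, tme_scores

logging.getLogger("bbbscore").setLevel(logging.ERROR)
logging.getLogger("bbbscore.tme_scores").setLevel(logging.ERROR)


def random_matrix(rng, n_genes, n_samples, log_transformed=True):
    values = pd.DataFrame(
        rng.normal(6.0, 2.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return io_formats.ExpressionMatrix(values, log_transformed=log_transformed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One shared synthetic cohort at generator defaults (n=200, seed 1),
    scored end to end; reused by recovery and reproduction tests."""
    cfg = synthetic_data.GeneratorConfig(n_samples=200, seed=1)
    matrix, clinical, truth = synthetic_data.simulate_cohort(cfg)
    logm = io_formats.log_transform(matrix)
    table = enrichment.score_all_cell_types(logm, truth.signatures, cfg.cell_types)
    bbb = tme_scores.bbb_score(table)
    estimate = tme_scores.estimate_like(logm, truth.stromal_set, truth.immune_set)
    return {
        "cfg": cfg,
        "matrix": matrix,
        "logm": logm,
        "clinical": clinical,
        "truth": truth,
        "table": table,
        "bbb": bbb,
        "estimate": estimate,
    }
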