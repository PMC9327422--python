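import numpy as np
import pandas as pd
import pytest

from amlsig.io_formats import (
    DrugResponseTable,
    KinaseSubstrateMap,
    MultiOmicCohort,
    OmicsMatrix,
    PPIEdgeList,
)
from amlsig.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """38-sample cohort with planted 5-feature protein signatures."""
    cfg = CohortConfig(seed=11, n_genes=60, n_drugs=3, missing_rate=0.0)
    cohort, response, truth = generate_cohort(cfg)
    return cohort, response, truth


@pytest.fixture()
def tiny_matrices():
    samples = ["S1", "S2", "S3", "S4", "S5"]
    rng = np.random.default_rng(0)
    prot = pd.DataFrame(
        rng.standard_normal((5, 4)), index=samples, columns=["GA", "GB", "GC", "GD"]
    )
    return OmicsMatrix("protein", prot)


@pytest.fixture()
def toy_ppi():
    edges = pd.DataFrame(
        [
            ("A", "B", 0.8),
            ("B", "C", 0.6),
            ("C", "D", 0.4),
            ("A", "D", 0.5),
            ("B", "K1", 0.7),
        ],
        columns=["node_a", "node_b", "confidence"],
    )
    return PPIEdgeList(edges=edges)


@pytest.fixture()
def toy_ks():
    pairs = pd.DataFrame(
        [("K1", "A-pS10"), ("K1", "B-pT20")], columns=["kinase", "site"]
    )
    return KinaseSubstrateMap(pairs=pairs)


@pytest.fixture()
def toy_response():
    auc = pd.DataFrame(
        {
            "S1": [50.0, 150.0, 90.0],
            "S2": [120.0, 160.0, 95.0],
            "S3": [80.0, 170.0, np.nan],
            "S4": [110.0, 105.0, 99.0],
        },
        index=["D1", "D2", "D3"],
    )
    return DrugResponseTable(auc=auc)
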