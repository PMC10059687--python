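import numpy as np
import pandas as pd
import pytest

from omixmod import (
    ExpressionMatrix,
    SimParams,
    generate_multiomics,
    integrate_multiomics,
    run_pipeline,
    write_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, sample_meta=None, unit="tpm"):
    """Small ExpressionMatrix from a dict of rows."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    if sample_meta is None:
        sample_meta = pd.DataFrame({
            "cell_class": ["progenitor"] * df.shape[1],
            "day": [40] * df.shape[1],
            "batch": ["b1"] * df.shape[1],
            "assay": ["rna"] * df.shape[1],
        }, index=df.columns)
    return ExpressionMatrix(df.astype(float), sample_meta, unit)


@pytest.fixture(scope="session")
def default_data():
    """One default-parameter synthetic multi-omics dataset (seed 101)."""
    params = SimParams(seed=101)
    return generate_multiomics(params, np.random.default_rng(101))


@pytest.fixture(scope="session")
def default_integrated(default_data):
    return integrate_multiomics(default_data)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline on a written default dataset; shared across tests."""
    root = tmp_path_factory.mktemp("pipeline")
    config = write_dataset(SimParams(seed=7), root / "dataset")
    results = run_pipeline(config, root / "out")
    return {"config": config, "results": results, "outdir": root / "out",
            "dataset": root / "dataset"}
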