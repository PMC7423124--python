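import numpy as np
import pandas as pd
import pytest

from refstab.cq_data import CqTable


def make_table(cq: dict[str, list[float]], timepoints=None, unit="hours",
               replicates=None) -> CqTable:
    """Small CqTable builder for tests: one sample per entry."""
    n = len(next(iter(cq.values())))
    timepoints = timepoints if timepoints is not None else list(range(n))
    replicates = replicates if replicates is not None else [1] * n
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"timepoint": [float(t) for t in timepoints],
         "timepoint_unit": unit, "group": None, "replicate": replicates},
        index=pd.Index(samples, name="sample_id"),
    )
    return CqTable(pd.DataFrame(cq, index=samples).T, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)


@pytest.fixture
def three_gene_quantities():
    """The worked 3-gene instance: A=(1,1,1), B=(1,2,1), C=(1,1,2)."""
    return pd.DataFrame(
        {"s1": [1.0, 1.0, 1.0], "s2": [1.0, 2.0, 1.0], "s3": [1.0, 1.0, 2.0]},
        index=["A", "B", "C"],
    )


def random_quantities(rng, n_genes, n_samples, spread=1.0):
    """Log-normal-ish positive quantity matrix."""
    logq = rng.normal(0.0, spread, size=(n_genes, n_samples))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(np.exp2(logq), index=genes, columns=samples)
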