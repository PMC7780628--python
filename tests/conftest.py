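import numpy as np
import pandas as pd
import pytest

from hololink.io import CountMatrix, SampleTable
from hololink.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def toy_counts() -> CountMatrix:
    df = pd.DataFrame(
        [[1, 2], [3, 4]], index=["f1", "f2"], columns=["s1", "s2"], dtype=np.int64
    )
    return CountMatrix(df)


@pytest.fixture
def design_samples():
    """12-sample 2x3 wild-type design: 2 genotypes x 3 treatments x 2 reps."""
    rows = []
    for g in ("G1", "G2"):
        for t in ("control", "glyphosate", "roundup"):
            for r in ("r1", "r2"):
                rows.append(
                    {
                        "sample_id": f"{g}_{t}_{r}",
                        "genotype": g,
                        "treatment": t,
                        "antibiotic": "wild_type",
                        "replicate": r,
                    }
                )
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but complete synthetic holobiont dataset."""
    cfg = SimulationConfig(
        n_genotypes=2,
        n_replicates_per_cell=3,
        n_genes=40,
        n_sotus=30,
        n_core_taxa=5,
        n_linked_sotus=2,
        depth_mean_expr=20_000,
        depth_mean_sotu=5_000,
        seed=42,
    )
    return generate_dataset(cfg)
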