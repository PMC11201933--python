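import numpy as np
import pandas as pd
import pytest

import coexsig as cx


@pytest.fixture(scope="session")
def planted():
    """One planted-module fixture shared across tests: counts, truth map,
    normalized log-CPM and a gene set that is 70% module-1."""
    plan = cx.ModulePlan(seed=1)
    counts, truth = cx.simulate_counts(plan)
    logcpm, norm = cx.normalize_pipeline(counts)
    sets = cx.simulate_gene_sets(
        truth,
        [cx.GeneSetSpec("SET_M1", size=40, module="module_1", module_fraction=0.7),
         cx.GeneSetSpec("SET_M1B", size=30, module="module_1", module_fraction=0.8),
         cx.GeneSetSpec("SET_NOISE", size=30)],
        seed=1,
    )
    return {"counts": counts, "truth": truth, "logcpm": logcpm,
            "norm": norm, "sets": sets}


@pytest.fixture()
def toy_logcpm():
    """Tiny deterministic log-scale matrix for rank-based operations."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(rng.normal(5, 2, size=(20, 12)),
                      index=[f"G{i:02d}" for i in range(20)],
                      columns=[f"S{j:02d}" for j in range(12)])
    return cx.ExpressionMatrix(values=df, stage=cx.LOG_CPM)
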