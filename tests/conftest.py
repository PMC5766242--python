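import numpy as np
import pandas as pd
import pytest

from chaperoscope import expression as ex
from chaperoscope import ontology as ont
from chaperoscope import synthetic as syn


@pytest.fixture(scope="session")
def chaperome():
    return ont.load_builtin_chaperome()


@pytest.fixture(scope="session")
def toy_mi():
    return syn.toy_method_ontology()


@pytest.fixture(scope="session")
def small_cohort():
    """3 tissues x (8+8) samples, 5 families x 8 genes, mixed programmed shifts."""
    spec = syn.CohortSpec(
        tissues=["T1", "T2", "T3"],
        n_tumor=8, n_normal=8,
        n_genes=120,
        families={f"F{i}": 8 for i in range(1, 6)},
        effects={"F1": 2.0, "F2": -2.0, "F3": 0.0, "F4": 1.0, "F5": -1.0},
        seed=11,
    )
    counts, annot, truth, fams = syn.simulate_cohort(spec)
    expr = ex.center_genes(ex.log_cpm(counts), annot, scope="per-tissue")
    return {"spec": spec, "counts": counts, "annot": annot, "truth": truth,
            "families": fams, "expr": expr}


@pytest.fixture()
def toy_expr():
    """Deterministic 4-gene x 6-sample expression matrix, one tissue."""
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(rng.normal(size=(4, 6)),
                        index=[1, 2, 3, 4],
                        columns=[f"s{i}" for i in range(6)])
    labels = np.array(["tumor"] * 3 + ["normal"] * 3)
    return ex.ExpressionMatrix(vals, centered=True), labels
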