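import numpy as np
import pandas as pd
import pytest

from coordshift.datatypes import ExpressionMatrix
from coordshift.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """120-gene neutral study (no planted age effects), 6 groups x 40."""
    cfg = SimulationConfig(n_genes=120, n_modules=4, seed=3)
    model, modules, expr, meta, truth = simulate_study(cfg)
    return {
        "config": cfg,
        "model": model,
        "modules": modules,
        "expr": expr,
        "meta": meta,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_expression(values: np.ndarray, genes=None, samples=None, space="residual"):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), space)


def make_meta(groups, ages=None):
    """Metadata from {group_label: [sample ids]}; ages default 25, 35, ..."""
    rows = []
    ages = ages or {g: 25.0 + 10 * i for i, g in enumerate(groups)}
    for g, samples in groups.items():
        for s in samples:
            rows.append({"sample_id": s, "age_group": g, "age_numeric": ages[g]})
    return pd.DataFrame(rows).set_index("sample_id")
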