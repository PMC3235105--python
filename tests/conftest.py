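import numpy as np
import pandas as pd
import pytest

from limbtx import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast fixture-sized design: 600 genes, full 55-array grid."""
    return SimConfig(n_genes=600, n_fl_identity=15, n_hl_identity=15,
                     n_categories=12, category_size_range=(8, 40), seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_de(small_bundle):
    from limbtx import run_all_contrasts
    return run_all_contrasts(small_bundle["matrix"], small_bundle["design"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_de_table(calls_by_contrast: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Hand-built minimal DE table: {contrast: {gene: call}}."""
    rows = []
    for contrast, calls in calls_by_contrast.items():
        for gene, call in calls.items():
            fc = 4.0 if call == "up" else (0.25 if call == "down" else 1.0)
            adj = 1e-5 if call in ("up", "down") else 0.5
            rows.append({"gene": gene, "contrast": contrast, "mean_A": 0.0,
                         "mean_B": 0.0, "log2fc": np.log2(fc), "fc": fc,
                         "t_mod": 0.0, "df": 10.0, "p": adj, "adj_p": adj,
                         "call": call, "degenerate": False})
    return pd.DataFrame(rows)
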