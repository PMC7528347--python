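import numpy as np
import pandas as pd
import pytest

from resadj import AdjustedTable, AdjustmentMap, SimConfig, simulate


@pytest.fixture
def six_row_table() -> AdjustedTable:
    """One continuous feature, one continuous covariate, continuous target."""
    df = pd.DataFrame(
        {
            "geneA": [1.0, 2.0, 3.5, 4.0, 5.5, 6.0],
            "c1": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
            "y": [2.0, 2.5, 4.0, 5.0, 6.5, 7.0],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    roles = {"geneA": "feature", "c1": "covariate", "y": "target"}
    kinds = {"geneA": "continuous", "c1": "continuous", "y": "continuous"}
    return AdjustedTable(df, roles, kinds)


@pytest.fixture
def random_table() -> AdjustedTable:
    """Seeded random table: 200 rows, 5 features, 3 covariates, 1 target."""
    rng = np.random.default_rng(42)
    m = 200
    data = {f"g{j}": rng.normal(size=m) for j in range(5)}
    data |= {f"c{j}": rng.normal(size=m) for j in range(3)}
    data["y"] = rng.normal(size=m)
    df = pd.DataFrame(data, index=pd.Index([f"s{i}" for i in range(m)], name="sample_id"))
    roles = {c: "feature" for c in data}
    for j in range(3):
        roles[f"c{j}"] = "covariate"
    roles["y"] = "target"
    kinds = {c: "continuous" for c in data}
    return AdjustedTable(df, roles, kinds)


@pytest.fixture
def random_map(random_table) -> AdjustmentMap:
    covs = [f"c{j}" for j in range(3)]
    amap = AdjustmentMap(
        entries=[(f"g{j}", covs) for j in range(5)],
        adjust_target=True,
        target_covariates=covs,
    )
    amap.validate(random_table)
    return amap


@pytest.fixture(scope="session")
def sim_default():
    """One default confounded simulation shared across tests."""
    return simulate(SimConfig())


def brute_force_residuals(v, C, train_rows, all_rows):
    """Independent oracle: pseudoinverse least squares fit on the training
    rows, predict-and-subtract over all requested rows."""
    v = np.asarray(v, dtype=float)
    C = np.asarray(C, dtype=float)
    train_rows = np.asarray(train_rows, dtype=int)
    all_rows = np.asarray(all_rows, dtype=int)
    design = np.column_stack([np.ones(len(train_rows)), C[train_rows]])
    beta = np.linalg.pinv(design) @ v[train_rows]
    design_all = np.column_stack([np.ones(len(all_rows)), C[all_rows]])
    return v[all_rows] - design_all @ beta
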