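import numpy as np
import pytest

import pharmrsm as pr


@pytest.fixture(scope="session")
def paper():
    return pr.fixtures()


@pytest.fixture(scope="session")
def table1(paper):
    return paper.table1


@pytest.fixture(scope="session")
def models(table1):
    return {name: pr.fit_quadratic(table1, name) for name in ("PS", "PDI", "ZP")}


@pytest.fixture(scope="session")
def paper_goals(table1):
    return pr.goals_from_table(
        table1, {"PS": "minimize", "PDI": "minimize", "ZP": "maximize"}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230405)


def normal_equations_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force OLS oracle: explicit normal equations solved by
    Gauss-Jordan elimination with partial pivoting (independent of the
    SVD path used by the fitter)."""
    A = X.T @ X
    b = X.T @ y
    n = len(b)
    aug = np.hstack([A.astype(float), b.reshape(-1, 1).astype(float)])
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(aug[col:, col])))
        aug[[col, pivot]] = aug[[pivot, col]]
        aug[col] /= aug[col, col]
        for row in range(n):
            if row != col:
                aug[row] -= aug[row, col] * aug[col]
    return aug[:, -1]


@pytest.fixture(scope="session")
def oracle():
    return normal_equations_oracle
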