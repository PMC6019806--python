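import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import HealthCheck, settings

from methexpr import SyntheticConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def ols_oracle(y: np.ndarray, X: np.ndarray):
    """Closed-form OLS via the normal equations, with two-sided t-tests.

    Independent of the package's fitting path; returns (beta, se, p, df).
    """
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    return beta, se, p, df


def build_design(x: np.ndarray, pheno_df: pd.DataFrame):
    """Treatment-coded design (intercept, meth, ERpos, BasalA, BasalB),
    dropping absent levels — built independently of the package."""
    cols = [np.ones(len(x)), np.asarray(x, dtype=float)]
    names = ["intercept", "meth"]
    if pheno_df["er_status"].nunique() > 1:
        cols.append((pheno_df["er_status"] == "ERpos").to_numpy(float))
        names.append("ERpos")
    present = [lv for lv in ("Luminal", "BasalA", "BasalB")
               if lv in set(pheno_df["subtype"])]
    if len(present) > 1:
        for lv in present[1:]:
            cols.append((pheno_df["subtype"] == lv).to_numpy(float))
            names.append(lv)
    return np.column_stack(cols), names


@pytest.fixture(scope="session")
def small_dataset():
    """20 genes with mixed pair-grid shapes, including long genes."""
    return generate_dataset(SyntheticConfig(
        n_genes=20, m_range=(1, 3), n_range=(2, 24), seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default one-probeset x one-probe study, seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))
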