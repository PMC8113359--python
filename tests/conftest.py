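import numpy as np
import pandas as pd
import pytest

from agesel.data_io import ExpressionMatrix
from agesel.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort under the default planted maps (fixed seed)."""
    cfg = CohortConfig(n_genes=300, seed=123)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def tiny_expression():
    """3 genes x 4 samples with a clean age gradient."""
    ages = [1.0, 2.0, 3.0, 4.0]
    values = pd.DataFrame(
        {
            "s1": [0.5, 2.0, 1.0],
            "s2": [1.0, 1.0, 1.0],
            "s3": [1.5, 2.0, 1.0],
            "s4": [2.0, 1.0, 1.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {"age": ages}, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
    )
    return ExpressionMatrix(values=values, samples=samples)


def brute_force_seg_integral(gamma: float, m: int, panels: int = 1_000_000) -> float:
    """Trapezoid oracle for the segregating-site integral (independent of the
    package's quadrature)."""
    p = np.linspace(0.0, 1.0, panels + 1)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if gamma > 0:
            r = np.expm1(-gamma * (1.0 - p)) / np.expm1(-gamma)
        elif gamma < 0:
            g = -gamma
            r = np.exp(-g * p) * np.expm1(-g * (1.0 - p)) / np.expm1(-g)
        else:
            r = 1.0 - p
        f = r / (p * (1.0 - p)) * (1.0 - p**m - (1.0 - p) ** m)
    f[0] = float(m)
    f[-1] = 0.0
    return float(np.trapezoid(f, p))


def brute_force_g_integral(ne_s: float, n: int, panels: int = 1_000_000) -> float:
    """Trapezoid oracle for the fixation-path integral."""
    x = np.linspace(0.0, 1.0, panels + 1)
    u = 1.0 - x
    arg = ne_s * u
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = -np.expm1(-arg) / arg
    fac[u == 0] = 1.0
    return float(np.trapezoid(x ** (n - 1) * fac, x))
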