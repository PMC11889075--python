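import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from irand import DGPConfig, TwoPointPanel, gen_nutrition_like, gen_panel


@pytest.fixture(scope="session")
def lcd_panel():
    """Moderate LCD-like panel (everyone treated at follow-up)."""
    return gen_panel(DGPConfig(n=200, sigma=1.0, treatment_design="lcd_like", seed=101))


@pytest.fixture(scope="session")
def bmi_panel():
    """Moderate panel with logistic treatment assignment at each visit."""
    return gen_panel(DGPConfig(n=300, sigma=1.0, treatment_design="bmi_like", seed=202))


@pytest.fixture(scope="session")
def nutrition_panel():
    return gen_nutrition_like(400, seed=303)


def toy_panel(rows: dict) -> TwoPointPanel:
    """Build a tiny panel from per-column lists (2 rows per individual)."""
    return TwoPointPanel(pd.DataFrame(rows))


def make_cross_section(seed, n, k=2, treated_frac=0.5):
    """Random small cross-section with both treatment classes guaranteed."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    n_treated = max(1, min(n - 1, int(round(treated_frac * n))))
    T = np.zeros(n)
    T[rng.choice(n, n_treated, replace=False)] = 1
    Y = rng.normal(size=n) + 2 * T
    return X, T, Y
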