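import numpy as np
import pandas as pd
import pytest

from histpheno.registry import default_registry
from histpheno.simulate import SimulationParams, simulate_trial


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_trial():
    """A modest unbalanced trial with injected outliers and a deviant year."""
    params = SimulationParams(
        n_accessions=150,
        year_span=(1995, 2014),
        mean_years_per_accession=4.36,
        mu=60.0,
        sigma2_g=1.0,
        sigma2_year=1.0,
        sigma2_e=1.0,
        record_outlier_rate=0.05,
        record_outlier_shift=8.0,
        year_cv_inflation={2005: 12.0},
        seed=11,
    )
    return simulate_trial(params)


@pytest.fixture(scope="session")
def clean_trial():
    """Outlier-free homoscedastic trial."""
    params = SimulationParams(
        n_accessions=150,
        year_span=(1995, 2014),
        sigma2_g=1.0,
        sigma2_year=1.0,
        sigma2_e=1.0,
        seed=12,
    )
    return simulate_trial(params)


def balanced_oneway(rng, n_groups, n_reps, mu=10.0, sd_g=2.0, sd_e=1.0):
    """Balanced one-way layout with known ANOVA estimators."""
    g = rng.normal(0, sd_g, n_groups)
    rows = []
    for i in range(n_groups):
        for _ in range(n_reps):
            rows.append(
                {"accession_id": f"G{i:02d}", "value": mu + g[i] + rng.normal(0, sd_e)}
            )
    return pd.DataFrame(rows)


def anova_oneway_components(df):
    """Closed-form balanced one-way ANOVA/REML estimators, truncated at 0.

    sigma2_g = (MSB - MSE) / r when positive; at the boundary the REML
    solution is sigma2_g = 0 with sigma2_e = total SS / (n - 1).
    """
    groups = df.groupby("accession_id")["value"]
    r = int(groups.size().iloc[0])
    means = groups.mean()
    msb = r * means.var(ddof=1)
    mse = groups.apply(lambda v: v.var(ddof=1)).mean()
    s2g = (msb - mse) / r
    if s2g > 0:
        return float(s2g), float(mse)
    return 0.0, float(df["value"].var(ddof=1))
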