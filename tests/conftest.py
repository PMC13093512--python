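import numpy as np
import pandas as pd
import pytest

from brainsim.synthetic_cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale configuration shared by fast tests."""
    return SimConfig(
        n_reference=30, n_incident=6, n_elevated=6,
        n_regions=12, n_visits=3, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg) -> pd.DataFrame:
    return generate_cohort(small_cfg)


def make_longitudinal(
    rng: np.random.Generator,
    n_subjects: int,
    n_visits: int = 3,
    predictors: dict | None = None,
    interaction: dict | None = None,
    intercept_sd: float = 0.5,
    residual_sd: float = 0.3,
) -> pd.DataFrame:
    """Minimal long-format dataset for mixed-model tests.

    ``predictors`` maps column name -> per-subject values; ``interaction``
    maps column name -> slope effect per unit predictor per year.
    """
    predictors = predictors or {}
    interaction = interaction or {}
    b0 = rng.normal(0.0, intercept_sd, n_subjects)
    ages = rng.uniform(65, 80, n_subjects)
    rows = []
    for i in range(n_subjects):
        for t in range(n_visits):
            slope = sum(
                interaction.get(name, 0.0) * vals[i]
                for name, vals in predictors.items()
            )
            y = b0[i] + slope * t + rng.normal(0.0, residual_sd)
            row = dict(
                subject_id=f"S{i:04d}", visit_time=float(t), y=y,
                age=float(ages[i]), sex=float(i % 2), education=16.0,
            )
            for name, vals in predictors.items():
                row[name] = float(vals[i])
            rows.append(row)
    return pd.DataFrame(rows)
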