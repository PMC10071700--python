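import numpy as np
import pandas as pd
import pytest

from metabias import GeneratorConfig, generate_corpus

# Frozen 12-record, 5-study fixture used for the REML oracle checks and the
# external cross-validation of the multilevel fit.  Values were drawn once
# from a three-level generating model (overall effect 0.3, between-study SD
# 0.25, observation SD 0.15) and frozen.
FIX12 = pd.DataFrame(
    {
        "y": [0.7086, 0.5804, 0.7924, 0.2546, 0.5645, 0.5779,
              0.7014, 0.1715, 0.1355, 0.3957, 0.216, 0.2954],
        "v": [0.0878, 0.0514, 0.0823, 0.0853, 0.0881, 0.0348,
              0.0908, 0.0506, 0.0874, 0.0174, 0.0651, 0.0752],
        "x": [0.1659, 0.4493, 0.2567, 0.4438, 0.2333, 0.2665,
              0.2998, 0.1649, 0.4518, 0.4634, 0.1519, 0.3787],
        "g": ["s1", "s1", "s2", "s2", "s2", "s3", "s3", "s4", "s4", "s4", "s5", "s5"],
    }
)


@pytest.fixture(scope="session")
def fix12():
    return FIX12.copy()


@pytest.fixture(scope="session")
def toy_corpus():
    """Small deterministic corpus covering all three metrics."""
    cfg = GeneratorConfig(
        n_meta=6,
        studies_per_meta=(8, 10),
        effects_per_study=(1, 3),
        metric="mixed",
        seed=7,
    )
    corpus, truth = generate_corpus(cfg)
    return corpus, truth


def make_regression_dataset(
    slope_err: float,
    slope_year: float,
    intercept: float = 0.3,
    n_studies: int = 8,
    seed: int = 0,
    metric: str = "Zr",
) -> pd.DataFrame:
    """Near-noiseless dataset with controlled uncertainty and year slopes.

    Effect sizes follow intercept + slope_err * se + slope_year * (year -
    year_latest) plus a whisper of noise, so the fitted detection slopes
    have the requested signs with certainty.
    """
    rng = np.random.default_rng(seed)
    rows = []
    years = np.linspace(2000, 2019, n_studies).astype(int)
    for j in range(n_studies):
        n = int(rng.integers(30, 120))
        var = 1.0 / (n - 3)
        se = np.sqrt(var)
        year = int(years[j])
        for i in range(2):
            es = (
                intercept
                + slope_err * se
                + slope_year * (year - years.max())
                + rng.normal(0, 1e-4)
            )
            rows.append(
                {
                    "meta_id": "MA001",
                    "study_id": f"S{j:02d}",
                    "obs_id": f"S{j:02d}_E{i}",
                    "metric": metric,
                    "es": es,
                    "var": var,
                    "se": se,
                    "n_e": np.nan,
                    "n_c": np.nan,
                    "n_total": n,
                    "year": year,
                }
            )
    return pd.DataFrame(rows)
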