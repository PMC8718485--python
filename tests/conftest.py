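import numpy as np
import pytest

from themewise.engine import EngineConfig
from themewise.metrics import SplitSpec
from themewise.prep import VariableDictionary, prepare
from themewise.synthetic import SyntheticConfig, ThemeSpec, generate_population


def small_config(seed: int = 0, n: int = 4000, signal: bool = True,
                 **overrides) -> SyntheticConfig:
    """Compact two-theme study: ~90 encoded features, strong effects."""
    themes = ()
    if signal:
        themes = (
            ThemeSpec("alpha", tuple(f"c{j:03d}" for j in range(0, 6)),
                      (1.6, 1.4, -1.2, 1.0, 0.9, 0.8),
                      within_theme_correlation=0.3),
            ThemeSpec("beta", tuple(f"c{j:03d}" for j in range(6, 12)),
                      (1.0, -0.9, 0.8, 0.7, 0.6, 0.55),
                      within_theme_correlation=0.3),
        )
    base = dict(n_respondents=n, n_continuous=40, n_categorical=12,
                levels_per_categorical=(3, 4, 5), themes=themes,
                n_duplicate_pairs=3, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


def fast_engine_config(seed: int = 0, **overrides) -> EngineConfig:
    base = dict(split=SplitSpec(seed=seed), cv_seed=seed, n_lambda=5,
                lambda_ratio=0.02, cv_tol=1e-2, fit_tol=1e-4)
    base.update(overrides)
    return EngineConfig(**base)


@pytest.fixture(scope="session")
def small_population():
    return generate_population(small_config(seed=7))


@pytest.fixture(scope="session")
def small_encoded(small_population):
    table, dct, gt = small_population
    enc = prepare(table, VariableDictionary.from_mapping(dct))
    return enc, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
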