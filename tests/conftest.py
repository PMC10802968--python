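import numpy as np
import pytest

from censimpute import (
    BSParams,
    LifetimeModel,
    PosteriorDraws,
    SurvivalDataset,
    WeibullParams,
)


@pytest.fixture
def toy_data() -> SurvivalDataset:
    """Four records: two events, two censored, with a covariate."""
    return SurvivalDataset(
        time=np.array([1.0, 2.5, 3.0, 4.0]),
        event=np.array([1, 0, 1, 0]),
        covariate=np.array([0, 1, 1, 0]),
    )


def degenerate_posterior(
    family: str, params, n: int = 10_000, regression: bool = False
) -> PosteriorDraws:
    """Posterior with every draw equal to a single parameter point."""
    model = LifetimeModel(family, regression=regression)
    draws = np.tile(np.asarray(params, dtype=float), (n, 1))
    return PosteriorDraws(model.parameter_names, draws, 1.0, 0, model)


@pytest.fixture
def weib_exp() -> WeibullParams:
    return WeibullParams(1.0, 0.25)


@pytest.fixture
def weib2() -> WeibullParams:
    return WeibullParams(2.0, 0.25)


@pytest.fixture
def bs_default() -> BSParams:
    return BSParams(0.5, 4.0)
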