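import numpy as np
import pytest

import spikequad as sq


@pytest.fixture(scope="session")
def basic_model() -> sq.SymmetricQuadrangleModel:
    return sq.SymmetricQuadrangleModel(30.0, 50.0, 10.0, 3.5, 4.0)


@pytest.fixture(scope="session")
def rendered_spike(basic_model):
    """One clean, straight, awnless render with ground truth."""
    spec = sq.SpikeRenderSpec(model=basic_model, scale=0.2, seed=11)
    img, masks, arclength = sq.render_spike(spec)
    return spec, img, masks, arclength


@pytest.fixture(scope="session")
def population_table():
    """Trait table of the eight study classes, 25 plants each (analytic mode)."""
    spec = sq.default_population_spec(n_per_class=25, seed=42)
    return sq.generate_population(spec, mode="traits")


def random_models(n: int, seed: int) -> list[sq.SymmetricQuadrangleModel]:
    rng = np.random.default_rng(seed)
    models = []
    while len(models) < n:
        x = rng.uniform(0.0, 80.0, size=3)
        y = rng.uniform(0.0, 10.0, size=2)
        if x.sum() > 0:
            models.append(sq.SymmetricQuadrangleModel(*x, *y))
    return models
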