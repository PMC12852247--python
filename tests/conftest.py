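import numpy as np
import pytest

from vocalid.synthetic import GeneratorConfig, default_within_sd


def make_null_config(seed: int, calls_per_day: int = 10, **kwargs) -> GeneratorConfig:
    """5 individuals, 3 contexts, no individual effect: every call drawn from
    one shared distribution."""
    return GeneratorConfig(
        n_individuals=5,
        n_nests=2,
        age_range_days=(11, 14),
        contexts={"beg": (1, 1), "rest": (1, 1), "unknown": (1, 1)},
        calls_per_individual_day=calls_per_day,
        seed=seed,
        **kwargs,
    )


def make_separated_config(seed: int, factor: float = 5.0, **kwargs) -> GeneratorConfig:
    """Individual offsets drawn with SD ``factor`` x the within-call SD."""
    return make_null_config(seed, offset_sd=default_within_sd() * factor, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_calls():
    from vocalid.synthetic import generate_dataset

    return generate_dataset(make_null_config(42))


@pytest.fixture
def separated_calls():
    from vocalid.synthetic import generate_dataset

    return generate_dataset(make_separated_config(43))
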