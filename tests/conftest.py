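import numpy as np
import pytest

from pointkin import (
    DesignSpec,
    EffectSpec,
    NoiseSpec,
    lowpass_filter,
    synthesize_trial,
)

ALL_CELLS = [
    (a, ad, s)
    for a in ("mind", "object")
    for ad in ("left", "right")
    for s in ("left", "middle", "right")
]


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free, variability-free mind/middle trial."""
    return synthesize_trial(
        ("mind", "left", "middle"),
        effects=EffectSpec.null(),
        noise=NoiseSpec.zero(),
        rng=0,
    )


@pytest.fixture(scope="session")
def clean_filtered(clean_trial):
    return lowpass_filter(clean_trial.series)


def make_trials(n, noise, effects=None, seed=0, cells=ALL_CELLS):
    """Deterministic stream of synthetic trials cycling through cells."""
    rng = np.random.default_rng(seed)
    effects = effects if effects is not None else EffectSpec()
    for i in range(n):
        yield synthesize_trial(cells[i % len(cells)], effects=effects, noise=noise, rng=rng)
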