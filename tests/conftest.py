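import numpy as np
import pytest

from trophlink import ConsumerGroupSpec, Scenario, generate_sources


@pytest.fixture
def triangle_sources():
    """Three well-separated sources spanning the iso-space plane."""
    return generate_sources(
        [(-21.0, 0.8, 4.0, 0.7), (-15.0, 0.9, 6.0, 0.8), (-19.0, 0.7, 12.0, 0.9)],
        labels=["som", "macroalgae", "zooplankton"],
    )


@pytest.fixture
def quad_sources():
    """Four sources with realistic (~1 per-mil) spreads."""
    return generate_sources(
        [
            (-22.0, 1.2, 4.0, 0.9),
            (-15.0, 1.0, 4.5, 1.1),
            (-14.5, 1.3, 12.0, 1.2),
            (-21.0, 0.9, 11.5, 1.4),
        ],
        labels=["som", "macroalgae", "benthos", "zooplankton"],
    )


def make_scenario(sources, diet, n=100, seed=0, process_sd=(0.3, 0.3), **group_kwargs):
    return Scenario(
        sources=sources,
        consumers=[ConsumerGroupSpec("consumer", diet=np.asarray(diet), n=n, **group_kwargs)],
        seed=seed,
        process_sd=process_sd,
    )
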