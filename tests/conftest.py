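import numpy as np
import pytest

from scoredrift import GeneratorSpec, ScoreHistogram, generate_reference, month_range


@pytest.fixture()
def rng():
    return np.random.default_rng(20230204)


@pytest.fixture()
def reference():
    """A synthetic retrospective-evaluation reference (FFDM, v1.2, Hologic)."""
    spec = GeneratorSpec(seed=2021, n_reports=13433, months=("1900-01",))
    return generate_reference(spec)


def make_hist(*counts):
    if len(counts) == 1 and not isinstance(counts[0], int):
        counts = tuple(counts[0])
    return ScoreHistogram.from_counts(counts)


@pytest.fixture()
def hist_factory():
    return make_hist


@pytest.fixture()
def small_stream():
    spec = GeneratorSpec(
        seed=7, n_reports=3000, months=month_range("2021-04", 3), center_id="C-X"
    )
    from scoredrift import generate_stream

    return spec, generate_stream(spec)
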