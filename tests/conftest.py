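import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from sangerbatch.trace_io import BASES, Chromatogram


def random_chromatogram(rng: np.random.Generator, n_bases: int | None = None) -> Chromatogram:
    """A structurally valid random trace (signals are arbitrary, not peak-shaped)."""
    n = int(rng.integers(0, 40)) if n_bases is None else n_bases
    length = max(10 * (n + 1), 20)
    order = "".join(rng.permutation(list(BASES)))
    positions = np.sort(rng.choice(length, size=n, replace=False)) if n else np.array([], dtype=int)
    return Chromatogram(
        source_name=f"rnd{rng.integers(1e6)}",
        channel_order=order,
        channels={b: rng.integers(0, 4000, size=length) for b in BASES},
        peak_positions=positions,
        bases="".join(rng.choice(list("ACGTN"), size=n)),
        qualities=rng.integers(0, 94, size=n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
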