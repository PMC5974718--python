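import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deltafst import GenotypePanel, MarkerInfo, MISSING

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_panel(calls, breeds=None, chrom="1", start_pos=1000, spacing=1000,
               alleles=("A", "G")):
    """Construct a small panel from a dosage matrix (row per sample)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if breeds is None:
        breeds = ["b1"] * n
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    markers = [
        MarkerInfo(f"m{j}", chroms[j], start_pos + j * spacing, *alleles)
        for j in range(m)
    ]
    sample_ids = [f"s{i}" for i in range(n)]
    return GenotypePanel(markers, sample_ids, list(breeds), calls)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_panel(rng):
    """20 samples x 50 markers, two breeds, ~5% missing calls."""
    freqs = rng.uniform(0.1, 0.9, 50)
    calls = rng.binomial(2, freqs, size=(20, 50)).astype(np.int8)
    calls[rng.random((20, 50)) < 0.05] = MISSING
    return make_panel(calls, breeds=["b1"] * 10 + ["b2"] * 10)
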