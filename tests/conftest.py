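import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mouflon.variants import GenotypeMatrix


def make_gm(dosages, samples=None, chrom="chr1", spacing=1000, ploidy="diploid",
            **site_cols):
    """Small GenotypeMatrix from a (sites x samples) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": spacing * (np.arange(n_sites) + 1),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    for k, v in site_cols.items():
        sites[k] = v
    return GenotypeMatrix(sites=sites, samples=list(samples), dosages=dosages,
                          ploidy=ploidy)


@pytest.fixture
def toy_gm():
    return make_gm(
        [[0, 1], [1, 2], [2, 0], [1, 1], [-1, 2]],
        samples=["a", "b"],
    )
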