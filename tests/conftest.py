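import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from centrorep.genome import GenomeLayout, OriginSet
from centrorep.replication_model import KineticsParams
from centrorep.synthetic_data import make_genome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_genome():
    """The package's default 4 x 400 kb synthetic genome."""
    return make_genome(seed=1)


@pytest.fixture
def params():
    return KineticsParams()


@pytest.fixture
def single_chrom_layout():
    return GenomeLayout((("chr1", 400_000),), {"chr1": 200_000})


def origin_set(rows):
    """Build an OriginSet from (chrom, pos, t_mean[, t_sigma, competence]) tuples."""
    full = [
        (r[0], r[1], r[2], r[3] if len(r) > 3 else 0.0, r[4] if len(r) > 4 else 1.0)
        for r in rows
    ]
    return OriginSet(
        pd.DataFrame(full, columns=["chrom", "pos", "t_mean", "t_sigma", "competence"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
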