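import numpy as np
import pandas as pd
import pytest

from nbgenome.platform import ProbeKind, ProbePlatform, make_uniform_platform
from nbgenome.profiles import CopyNumberProfile


@pytest.fixture(scope="session")
def oligo_platform():
    """~2000 evenly spaced oligo probes over the autosomes (fast)."""
    return make_uniform_platform(2000, ProbeKind.OLIGO)


@pytest.fixture(scope="session")
def bac_platform():
    return make_uniform_platform(1000, ProbeKind.BAC)


@pytest.fixture(scope="session")
def tiny_platform():
    """Two chromosomes, 20 probes each at 10 Mb spacing (hand-checkable)."""
    rows = []
    for chrom in (1, 2):
        for i in range(20):
            rows.append({"chrom": chrom, "pos": 5_000_000 + i * 10_000_000})
    return ProbePlatform(probe_kind=ProbeKind.OLIGO,
                         probes=pd.DataFrame(rows))


def make_profile(platform, values=None, tumor_id="T"):
    if values is None:
        values = np.zeros(platform.n_probes)
    return CopyNumberProfile(tumor_id, platform, np.asarray(values, float))


@pytest.fixture
def flat_profile(tiny_platform):
    return make_profile(tiny_platform)
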