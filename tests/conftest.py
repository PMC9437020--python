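import numpy as np
import pandas as pd
import pytest

from nucleotune import FragmentSet, pileup, simulate


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic dataset (3 x 2 Mb, 5e4 fragments/stage, seed 7)."""
    return simulate.generate()


@pytest.fixture(scope="session")
def final_stage_track(default_fixture):
    """Occupancy pileup of the last (most occupied) synthetic stage."""
    stage = default_fixture.spec.stages[-1]
    return pileup(default_fixture.fragments[stage])


def make_fragset(frags, chrom_sizes, **kw):
    df = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    return FragmentSet(df, chrom_sizes=chrom_sizes, **kw)


@pytest.fixture
def toy_fragset():
    """Ten disjoint fragments on a 10-kb single-chromosome genome."""
    frags = [("chr1", 1000 * i + 200, 1000 * i + 380) for i in range(10)]
    return make_fragset(frags, {"chr1": 10_000})
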