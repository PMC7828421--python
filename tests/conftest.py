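import math

import pandas as pd
import pytest

import mitohet as mh
from mitohet.io import AlleleCountTable

# uniform position-in-read summaries for 100-bp reads
RP_MEAN = 50.5
RP_SD = math.sqrt((100**2 - 1) / 12.0)


def make_table(sample_id: str, rows) -> AlleleCountTable:
    """rows: (pos, base, strand, count[, rp_mean, rp_sd])."""
    full = []
    for r in rows:
        if len(r) == 4:
            full.append((*r, RP_MEAN, RP_SD))
        else:
            full.append(tuple(r))
    df = pd.DataFrame(
        full, columns=["pos", "base", "strand", "count", "read_pos_mean", "read_pos_sd"]
    )
    return AlleleCountTable(sample_id=sample_id, df=df)


def het_position_rows(pos, major, minor, depth, maf, rp_minor=None):
    """Balanced-strand rows for one heteroplasmic position."""
    n_minor = int(round(maf * depth))
    n_major = depth - n_minor
    mean, sd = (rp_minor or (RP_MEAN, RP_SD))
    rows = [
        (pos, major, "forward", n_major // 2, RP_MEAN, RP_SD),
        (pos, major, "reverse", n_major - n_major // 2, RP_MEAN, RP_SD),
        (pos, minor, "forward", n_minor // 2, mean, sd),
        (pos, minor, "reverse", n_minor - n_minor // 2, mean, sd),
    ]
    return [r for r in rows if r[3] > 0]


@pytest.fixture(scope="session")
def reference():
    return mh.load_reference()


@pytest.fixture(scope="session")
def roster():
    return mh.load_table1_fixture()


@pytest.fixture(scope="session")
def table2_sites():
    return mh.load_table2_fixture()


@pytest.fixture(scope="session")
def recon_cohort(roster):
    return mh.reconstruct_cohort()


@pytest.fixture(scope="session")
def recon_calls(recon_cohort, roster):
    return mh.call_cohort(recon_cohort, families=roster.families())
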