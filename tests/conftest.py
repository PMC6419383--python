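import numpy as np
import pandas as pd
import pytest

import methworks as mw


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard two-group sequencing cohort with every planted effect."""
    return mw.generate_fixture(mw.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def null_fixture():
    """A cohort with no planted effects (pure baseline autosomal CpGs)."""
    return mw.generate_fixture(mw.null_spec(n_sites=2000, seed=3))


@pytest.fixture()
def tiny_dataset():
    """4 sites x 3 samples, handmade values, with coverage."""
    sites = mw.make_site_table(
        ["chr1", "chr1", "chr2", "chrX"], [100, 200, 50, 10], "*"
    )
    samples = pd.DataFrame(
        {"group": ["a", "a", "b"]}, index=pd.Index(["s1", "s2", "s3"], name="sample_id")
    )
    beta = np.array(
        [
            [0.1, 0.2, 0.3],
            [0.0, 1.0, 0.5],
            [np.nan, 0.4, 0.6],
            [0.9, 0.8, 0.7],
        ]
    )
    coverage = np.array(
        [
            [10, 20, 30],
            [5, 5, 5],
            [0, 8, 2],
            [4, 4, 4],
        ],
        dtype=float,
    )
    # dataset rows follow the sorted site order (chr1:100, chr1:200, chr2:50, chrX:10)
    return mw.MethylationDataset(
        sites=sites, samples=samples, beta=beta, coverage=coverage, platform="rrbs"
    )


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
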