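import numpy as np
import pandas as pd
import pytest

import cnsig


@pytest.fixture(scope="session")
def toy_build():
    return cnsig.load_genome_build("toy")


@pytest.fixture(scope="session")
def scheme():
    return cnsig.default_scheme()


@pytest.fixture(scope="session")
def default_cohort(scheme):
    """The simulator's default 200-sample cohort, tallied, with ground truth."""
    config = cnsig.SimConfig()  # 200 samples, 5 processes, seed 1
    profiles, truth = cnsig.simulate_cohort(config, scheme=scheme)
    catalog = cnsig.tally_cn_catalog(profiles, config.genome, scheme)
    return profiles, truth, catalog


def make_profile(sample="S1", chrom_cn=None, seg_len=1_000_000):
    """Profile from per-chromosome cn lists, contiguous equal-length segments.

    chrom_cn: dict chromosome -> list of integer copy numbers.
    """
    rows = []
    for chrom, cns in chrom_cn.items():
        pos = 1
        for cn in cns:
            rows.append({"chromosome": chrom, "start": pos, "end": pos + seg_len - 1, "cn": cn})
            pos += seg_len
    return cnsig.CNProfile(sample=sample, segments=pd.DataFrame(rows))


def random_toy_profile(rng, sample="R", build=None):
    """Random normalized profile on the toy build for oracle comparisons."""
    if build is None:
        build = cnsig.load_genome_build("toy")
    rows = []
    for chrom in build.chromosomes:
        length = build.lengths[chrom]
        n_seg = int(rng.integers(1, 12))
        cuts = np.sort(rng.choice(np.arange(2, length), size=n_seg - 1, replace=False))
        bounds = np.concatenate([[1], cuts, [length + 1]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {"chromosome": chrom, "start": int(lo), "end": int(hi) - 1,
                 "cn": int(rng.integers(0, 10))}
            )
    prof = cnsig.CNProfile(sample=sample, segments=pd.DataFrame(rows))
    return cnsig.normalize_profile(prof)
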