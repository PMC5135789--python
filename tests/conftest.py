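import numpy as np
import pytest

from dynameth.genomic_io import (AnnotationTrack, GenomicInterval,
                                 SampleCallSet)
from dynameth.panel_design import CandidateRegion


@pytest.fixture
def small_callset():
    import pandas as pd

    df = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [100, 250, 50],
        "meth_reads": [3, 7, 0],
        "total_reads": [10, 7, 4],
    })
    return SampleCallSet("s1", df)


@pytest.fixture
def enhancer_track():
    return AnnotationTrack("enhancers", [
        GenomicInterval("chr1", 900, 1400),
        GenomicInterval("chr2", 0, 500),
    ])


def make_candidate(chrom="chr1", start=1000, end=1200, name="r1",
                   source="setA", sample_levels=None, cpg_levels=None,
                   repeat_frac=0.1):
    """Hand-buildable candidate region with sensible defaults."""
    if sample_levels is None:
        sample_levels = {"A": 0.2, "B": 0.8}
    if cpg_levels is None:
        cpg_levels = {"A": [0.1, 0.2, 0.3], "B": [0.8, 0.7, 0.9]}
    return CandidateRegion(GenomicInterval(chrom, start, end, name), source,
                           sample_levels, cpg_levels, repeat_frac)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
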