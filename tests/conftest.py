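import pytest

from parpibench.genome import Chromosome, GenomeBuild, load_hg19
from parpibench.segments import Segment, SegmentProfile

MB = 1_000_000


@pytest.fixture(scope="session")
def hg19():
    return load_hg19()


@pytest.fixture(scope="session")
def toy_build():
    """Two 100 Mb chromosomes with a 48-52 Mb centromere each."""
    return GenomeBuild(
        "toy",
        [
            Chromosome("chr1", 100 * MB, 48 * MB, 52 * MB),
            Chromosome("chr2", 100 * MB, 48 * MB, 52 * MB),
        ],
    )


def make_profile(build, segs, sample_id="S1"):
    """Segments given as (chrom, start_mb, end_mb, log2[, major, minor])."""
    out = []
    for s in segs:
        chrom, start, end, log2 = s[:4]
        major, minor = (s[4], s[5]) if len(s) > 4 else (None, None)
        out.append(
            Segment(chrom, int(start * MB), int(end * MB), log2, major, minor)
        )
    return SegmentProfile(sample_id, out, build)


@pytest.fixture
def profile_factory(toy_build):
    def factory(segs, sample_id="S1", build=toy_build):
        return make_profile(build, segs, sample_id)

    return factory
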