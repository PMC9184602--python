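import numpy as np
import pandas as pd
import pytest

from hrdkit.config import PipelineConfig
from hrdkit.genome import GenomeBuild, default_build
from hrdkit.segments import SegmentProfile


@pytest.fixture(scope="session")
def build() -> GenomeBuild:
    return default_build()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def toy_build() -> GenomeBuild:
    """One 200 Mb chromosome with a centromere at 95-105 Mb."""
    return GenomeBuild(
        pd.DataFrame(
            {
                "chrom": ["chr1"],
                "length": [200_000_000],
                "centromere_start": [95_000_000],
                "centromere_end": [105_000_000],
            }
        )
    )


def make_profile(rows, sample="S1") -> SegmentProfile:
    """rows: list of (chrom, start, end, a, b)."""
    return SegmentProfile(
        sample,
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "a", "b"]),
    )


@pytest.fixture
def diploid(toy_build) -> SegmentProfile:
    return make_profile([("chr1", 1, 200_000_000, 1, 1)])
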