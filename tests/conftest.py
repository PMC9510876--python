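import numpy as np
import pandas as pd
import pytest

from cardiosplice.annotation import TranscriptModel


@pytest.fixture
def two_transcript_gene() -> list[TranscriptModel]:
    """T1 exons [0,100) [200,300); T2 exons [0,100) [250,300)."""
    return [
        TranscriptModel("G", "T1", "chr1", "+", ((0, 100), (200, 300))),
        TranscriptModel("G", "T2", "chr1", "+", ((0, 100), (250, 300))),
    ]


@pytest.fixture
def tissue_frame() -> pd.DataFrame:
    """Five tissues; geneA heart-enriched 10x, geneB uniform, geneC the
    hand-computed mixed-ratio case."""
    return pd.DataFrame(
        {
            "heart": [10.0, 3.0, 8.0],
            "t1": [1.0, 3.0, 2.0],
            "t2": [1.0, 3.0, 4.0],
            "t3": [1.0, 3.0, 8.0],
            "t4": [1.0, 3.0, 1.0],
        },
        index=["geneA", "geneB", "geneC"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)
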