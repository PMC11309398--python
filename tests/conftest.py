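import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from synloc import CountDataset, TranscriptModel


def make_dataset(counts: np.ndarray, fraction=None, condition=None) -> CountDataset:
    """CountDataset from a bare matrix with default alternating factors."""
    G, n = counts.shape
    samples = [f"s{i + 1}" for i in range(n)]
    if fraction is None:
        fraction = ["synaptosome" if i < n // 2 else "homogenate" for i in range(n)]
    if condition is None:
        condition = ["case" if i % 2 == 0 else "control" for i in range(n)]
    return CountDataset(
        counts=pd.DataFrame(
            counts, index=[f"f{i + 1}" for i in range(G)], columns=samples
        ),
        fraction=pd.Series(fraction, index=samples),
        condition=pd.Series(condition, index=samples),
    )


def make_transcript(exon_seqs, transcript_id="tx1", gene_id="g1", strand="+",
                    gap=50):
    """TranscriptModel with arbitrary genomic coordinates spaced by ``gap``."""
    exons = []
    pos = gap
    for seq in exon_seqs:
        exons.append((pos, pos + len(seq)))
        pos += len(seq) + gap
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_name=gene_id.upper(),
        strand=strand,
        exons=tuple(exons),
        exon_sequences=tuple(exon_seqs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
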