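import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from splicemark.model import ExonRegion, GenomicInterval, TranscriptModel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_transcript(
    exon_coords,
    strand="+",
    chrom="chr1",
    transcript_id="TX1",
    gene_id="G1",
    phases=None,
):
    """Transcript from genomic exon coordinates (ordered genomically)."""
    coords = sorted(exon_coords)
    ordered = coords if strand == "+" else coords[::-1]
    if phases is None:
        phases = [-1] * len(ordered)
    exons = [
        ExonRegion(
            interval=GenomicInterval(chrom, s, e, strand), index=i + 1, phase=p
        )
        for i, ((s, e), p) in enumerate(zip(ordered, phases))
    ]
    return TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, strand=strand, exons=exons
    )


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_exon_transcript():
    """Two 300-nt exons separated by a 100-nt intron, forward strand."""
    return make_transcript([(100, 400), (500, 800)], phases=[0, 0])


@pytest.fixture
def toy_genome(two_exon_transcript, rng):
    return {"chr1": random_dna(rng, 1000)}
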