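import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    from exciseqc.scenarios import default_gene_model

    return default_gene_model()


@pytest.fixture(scope="session")
def pair(model):
    from exciseqc.scenarios import default_guide_pair

    return default_guide_pair(model)


@pytest.fixture(scope="session")
def short_design():
    from exciseqc import scenarios

    return scenarios.short_design()


@pytest.fixture(scope="session")
def long_design():
    from exciseqc import scenarios

    return scenarios.long_design()


def make_toy_model(exon_lengths=(100, 63, 100), intron=200, flank=100, contig="toy"):
    """Small synthetic gene model for unit tests (deterministic sequence)."""
    import numpy as np

    from exciseqc.gene_model import GeneModel, GenomicInterval

    rng = np.random.default_rng(42)
    exons = []
    pos = flank
    for ln in exon_lengths:
        exons.append((pos, pos + ln))
        pos += ln + intron
    total = pos - intron + flank
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, total))
    return GeneModel(
        gene_id="toy1",
        locus=GenomicInterval(contig, 0, total, "+"),
        sequence=seq,
        exons=tuple(GenomicInterval(contig, s, e, "+") for s, e in exons),
        coding=tuple(True for _ in exons),
    )
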