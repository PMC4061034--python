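import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    settings(deadline=None, derandomize=True,
             suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("deterministic")

from famvar import SimulationConfig, simulate_family_bundle  # noqa: E402
from famvar.consequence import TranscriptModel  # noqa: E402


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic desk-scale bundle shared across tests."""
    return simulate_family_bundle(
        SimulationConfig(seed=11, n_variants_per_sample=2000))


@pytest.fixture
def toy_transcript_plus():
    # two coding exons (9 + 6 bp) with an intron; starts ATG, ends TAA
    return TranscriptModel(
        gene="TOY1", chrom="chr1", strand="+",
        cds_intervals=[(101, 109), (201, 206)],
        cds_sequence="ATGAAACCTGGGTAA")


@pytest.fixture
def toy_transcript_minus(toy_transcript_plus):
    """Mirror of the + strand toy gene on the - strand.

    Genomic coordinates are reflected around 1000 so exon j of the + model
    maps to interval (1000-end, 1000-start); the sense-strand CDS sequence
    is unchanged.
    """
    plus = toy_transcript_plus
    intervals = [(1000 - e, 1000 - s) for s, e in plus.cds_intervals]
    return TranscriptModel(
        gene="TOY1R", chrom="chr1", strand="-",
        cds_intervals=intervals, cds_sequence=plus.cds_sequence)
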