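import pytest

from hapolish.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def study_run():
    """One full pipeline run at the study conditions.

    A 2 x 1 Mb synthetic diploid with ~1 injected error / 50 kb per
    haplotype, two 25 kb collapsed (falsely homozygous) intervals, 40x
    HiFi-like and 15x UL-like reads.  Shared across tests because the run
    takes a few minutes.
    """
    return run_pipeline(PipelineConfig(seed=20260926))


@pytest.fixture(scope="session")
def small_run():
    """A faster 300 kb end-to-end run for pipeline-level behaviour tests."""
    return run_pipeline(PipelineConfig(seed=7, contig_length=300_000, loh_count=1))
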