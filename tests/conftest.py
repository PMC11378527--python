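"""Shared fixtures: synthetic bundles reused across test modules."""

import pytest
from hypothesis import settings

from lrrshuffle import SimConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


def noiseless_config() -> SimConfig:
    """Noiseless cohort: >=5 shuffling genes (runs incl. 16 and 49),
    >=10 negatives, genes on both strands, zero substitution rates."""
    return SimConfig(
        seed=0,
        n_roco_genes=5,
        repeats_per_gene=(16, 49, 6, 8, 10),
        n_lrr_only_genes=2,
        n_roc_only_genes=4,
        n_plain_genes=3,
        n_wrong_length_genes=2,
        n_wrong_phase_genes=2,
        synonymous_rate=0.0,
        nonsynonymous_rate=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate(noiseless_config())


@pytest.fixture(scope="session")
def default_bundle():
    return generate(SimConfig(seed=2))


@pytest.fixture(scope="session")
def splice_bundle():
    """One 16-repeat gene forced to carry 9 distinct splice variants."""
    cfg = SimConfig(seed=5, n_roco_genes=1, repeats_per_gene=(16,),
                    n_transcripts_fixed=9, n_lrr_only_genes=0,
                    n_roc_only_genes=0, n_plain_genes=1,
                    n_wrong_length_genes=0, n_wrong_phase_genes=0,
                    synonymous_rate=0.0, nonsynonymous_rate=0.0)
    return generate(cfg)
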