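import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from snapmap import hapcall, simcross  # noqa: E402


@pytest.fixture(scope="session")
def noisy_cross():
    """Default-condition cross: 1% genotype error, 10% distal missingness."""
    cfg = simcross.SimConfig(seed=7)
    genome, truth, mat, phen = simcross.simulate_cross(cfg)
    return cfg, genome, truth, mat, phen


@pytest.fixture(scope="session")
def clean_cross():
    """Noise-free cross for exact round-trip checks."""
    cfg = simcross.SimConfig(seed=11, error_rate=0.0, missing_rate=0.0)
    genome, truth, mat, phen = simcross.simulate_cross(cfg)
    return cfg, genome, truth, mat, phen


@pytest.fixture(scope="session")
def clean_loci(clean_cross):
    """Informative called loci of the clean cross."""
    _, _, _, mat, _ = clean_cross
    loci = hapcall.call_loci(mat)
    return hapcall.informative_loci(hapcall.filter_loci(loci))


def truth_code_for(genome, truth, locus):
    """True species codes of the simulated locus nearest a called locus."""
    sel = genome.loci["chrom"] == locus.chrom
    starts = genome.loci.loc[sel, "start"].to_numpy()
    idx = genome.loci.index[sel].to_numpy()
    j = idx[np.argmin(np.abs(starts - locus.start))]
    return truth.species_code[:, j]
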