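import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose the _oracles helpers

from braya import synthdata as sd


@pytest.fixture(scope="session")
def genotype_sim():
    """Three clonal clusters with between-cluster 1-IBS targets of 10-11%."""
    return sd.simulate_genotypes(sd.GenotypeSimConfig(seed=11, n_snps=3000))


@pytest.fixture(scope="session")
def timm_sim():
    """Study-shaped T_imm records (23 clones, 4 runs, 6 replicates) with truth."""
    return sd.simulate_timm(sd.TimmSimConfig(seed=7))


@pytest.fixture(scope="session")
def small_traces():
    """Noiseless, run-effect-free respirometry design for exact-recovery checks."""
    cfg = sd.TraceSimConfig(
        seed=5, noise_sd=0.0, run_effect_sd=0.0, runs_per_batch=2,
        clones_per_batch=(4, 5), rate_sd=0.0,
    )
    return sd.simulate_traces(cfg)
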