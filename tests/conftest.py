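import numpy as np
import pandas as pd
import pytest

from pmdkit.simulate import (
    ArchitectureConfig, CohortConfig, generate_architecture, generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_arch():
    """One 2 Mb autosome plus a 1.5 Mb X with CGIs."""
    cfg = ArchitectureConfig(
        seed=11, n_chromosomes=1, chrom_length=2_000_000,
        x_length=1_500_000, n_x_cgis=30,
    )
    return generate_architecture(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """8 vs 8 cohort on a small genome, with a planted DMR and mixed sexes."""
    arch_cfg = ArchitectureConfig(
        seed=5, n_chromosomes=1, chrom_length=2_000_000,
        x_length=1_000_000, n_x_cgis=20,
    )
    cohort_cfg = CohortConfig(seed=5, n_asd=8, n_td=8)
    return generate_cohort(arch_cfg, cohort_cfg)


def random_track_frame(rng, n=200, chroms=("chr1", "chr2"), max_pos=100_000):
    """Random valid CpG count frame, unique sorted positions per chromosome."""
    frames = []
    for chrom in chroms:
        pos = np.sort(rng.choice(max_pos, size=n, replace=False))
        total = rng.integers(1, 30, size=n)
        meth = rng.binomial(total, rng.uniform(0.2, 0.9))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "total": total}))
    return pd.concat(frames, ignore_index=True)
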