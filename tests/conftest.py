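import numpy as np
import pytest

from fenclone.io_formats import GenotypeTable, SampleRecord, canonical_pair
from fenclone.robust_bayes import Schedule
from fenclone.synthetic_data import SimulationConfig, simulate_fen


def build_table(plots: dict[str, list[tuple]], loci: list[str]) -> GenotypeTable:
    """Build a GenotypeTable from {plot: [genotype, ...]} where a genotype is
    a tuple of (a, b) allele pairs, one per locus (None = missing call)."""
    samples = []
    for plot, genotypes in plots.items():
        for i, geno in enumerate(genotypes, start=1):
            alleles = {
                locus: canonical_pair(*pair)
                for locus, pair in zip(loci, geno)
            }
            samples.append(SampleRecord(f"{plot}-{i:02d}", plot, i, alleles))
    return GenotypeTable(samples=samples, loci=list(loci))


def random_plot_table(rng: np.random.Generator, n_samples: int = 12,
                      n_loci: int = 3, max_alleles: int = 4,
                      missing_prob: float = 0.0) -> GenotypeTable:
    genotypes = []
    for _ in range(n_samples):
        geno = []
        for l in range(n_loci):
            pool = [100 + 10 * l + 2 * j for j in range(max_alleles)]
            a, b = rng.choice(pool), rng.choice(pool)
            a = None if rng.uniform() < missing_prob else int(a)
            b = None if rng.uniform() < missing_prob else int(b)
            geno.append((a, b))
        genotypes.append(tuple(geno))
    return build_table({"p1": genotypes}, [f"L{l}" for l in range(n_loci)])


@pytest.fixture(scope="session")
def default_fen():
    """One default synthetic fen (16 plots x 20 subplots, 6 loci)."""
    return simulate_fen(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def clean_fen():
    """Synthetic fen without null-allele dropout (exact recovery expected)."""
    return simulate_fen(SimulationConfig(seed=23, dropout_prob=0.0))


@pytest.fixture(scope="session")
def fast_schedule():
    """Light MCMC schedule for tests that only need a rough posterior."""
    return Schedule(adapt=300, burnin=500, saved_total=4000, ess_target=0.0)
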