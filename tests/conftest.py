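import numpy as np
import pandas as pd
import pytest

from rohscan.data import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SnpMap


def make_map(positions_by_chrom: dict[str, list[int]]) -> SnpMap:
    records = []
    k = 0
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            records.append((chrom, int(p), f"s{k}", "A", "G"))
            k += 1
    return SnpMap.from_records(records, sort=True)


def make_dataset(positions_by_chrom, genotypes, populations=None) -> GenotypeDataset:
    """Build a dataset from a per-chromosome position dict and a genotype
    matrix whose columns follow the concatenated (sorted) map order."""
    snp_map = make_map(positions_by_chrom)
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    populations = populations or ["POP"] * n
    samples = pd.DataFrame({
        "sample_id": [f"ind{i}" for i in range(n)],
        "population": populations,
    })
    return GenotypeDataset(map=snp_map, samples=samples, genotypes=genotypes)


def random_genotype_vector(rng, n, p_target=0.75, p_opposite=0.2,
                           target_is_hom=True):
    """Random genotype states with tunable target/opposite/missing mix."""
    u = rng.random(n)
    if target_is_hom:
        target = np.where(rng.random(n) < 0.5, HOM_A, HOM_B)
        opposite = np.full(n, HET)
    else:
        target = np.full(n, HET)
        opposite = np.where(rng.random(n) < 0.5, HOM_A, HOM_B)
    g = np.where(u < p_target, target,
                 np.where(u < p_target + p_opposite, opposite, MISSING))
    return g.astype(np.int8)


def random_positions(rng, n, mean_spacing=40_000, big_gap_prob=0.02,
                     big_gap=1_500_000):
    """Strictly increasing positions with occasional gaps above 1 Mb."""
    steps = rng.integers(1, 2 * mean_spacing, size=n)
    big = rng.random(n) < big_gap_prob
    steps = np.where(big, big_gap + rng.integers(0, 500_000, size=n), steps)
    return np.cumsum(steps) + 1


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
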