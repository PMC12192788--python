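"""Consecutive-SNP detection of runs of homozygosity and heterozygosity.

The scanner walks markers in map order on one chromosome for one individual.
A run is a block of consecutive markers in which every marker is in the
target state, a tolerated opposite state, or missing; opposite and missing
markers are bounded by per-run allowances; no adjacent-marker gap exceeds
``max_gap_bp``; and both ends of the emitted run are called in the target
state (tolerated markers are trimmed from the flanks, so allowances can
never extend a run's span).  Blocks are grown greedily from the left — the
convention of the consecutive (non-sliding-window) method — so emitted runs
are pairwise disjoint; when an allowance is exhausted the scan resumes after
the violating marker.  A run is reported only if it spans at least
``min_snps`` markers and ``end_bp − start_bp ≥ min_length_bp``.

For ROH the target state is homozygous (either homozygote) and the opposite
state heterozygous; for ROHet the roles are swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .data import HET, MISSING, GenotypeDataset, SHEEP_AUTOSOMES


class TargetState(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class RunConfig:
    """Rule-set for the consecutive run scanner.

    Attributes
    ----------
    target_state : TargetState
        Genotype state the run is made of.
    min_snps : int
        Minimum number of markers spanned (tolerated markers included).
    min_length_bp : int
        Minimum run length, with length defined as ``end_bp − start_bp``.
    max_gap_bp : int
        Maximum distance between adjacent markers inside a run.
    max_opposite : int
        Opposite-state calls tolerated per run.
    max_missing : int
        Missing calls tolerated per run.
    """

    target_state: TargetState
    min_snps: int
    min_length_bp: int
    max_gap_bp: int
    max_opposite: int
    max_missing: int

    def __post_init__(self):
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be > 0")
        if self.max_opposite < 0 or self.max_missing < 0:
            raise ValueError("allowances must be >= 0")


def default_roh_config() -> RunConfig:
    """ROH preset for ~50k-SNP arrays: 30 SNPs, 0.5 Mb, 1 Mb gap, 1 het,
    1 missing allowed."""
    return RunConfig(TargetState.HOMOZYGOUS, 30, 500_000, 1_000_000, 1, 1)


def default_rohet_config() -> RunConfig:
    """ROHet preset: 15 SNPs, 1 Mb, 1 Mb gap, 3 homozygous, 2 missing
    allowed."""
    return RunConfig(TargetState.HETEROZYGOUS, 15, 1_000_000, 1_000_000, 3, 2)


@dataclass(frozen=True)
class RunSegment:
    """One detected run: 1-based inclusive first/last target-state SNP."""

    sample_id: str
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_opposite: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


# marker classes relative to the target state
_TARGET, _OPPOSITE, _MISS = 0, 1, 2


def _classify(genotypes: np.ndarray, target: TargetState) -> np.ndarray:
    cls = np.empty(len(genotypes), dtype=np.int8)
    is_miss = genotypes == MISSING
    is_het = genotypes == HET
    if target == TargetState.HOMOZYGOUS:
        cls[:] = _OPPOSITE
        cls[~is_het & ~is_miss] = _TARGET
    else:
        cls[:] = _TARGET
        cls[~is_het & ~is_miss] = _OPPOSITE
    cls[is_miss] = _MISS
    return cls


def detect_runs_one(
    genotypes: np.ndarray,
    positions: np.ndarray,
    config: RunConfig,
    sample_id: str = "",
    population: str = "",
    chromosome: str = "",
) -> list[RunSegment]:
    """Detect runs on one chromosome of one individual.

    ``genotypes`` and ``positions`` must be aligned, with positions strictly
    increasing.  Returns runs sorted by start, pairwise disjoint.
    """
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions, dtype=np.int64)
    if len(genotypes) != len(positions):
        raise ValueError("genotype vector and positions differ in length")
    if len(positions) > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")

    cls = _classify(genotypes, config.target_state)
    n = len(cls)
    runs: list[RunSegment] = []
    i = 0
    while i < n:
        # seed: next target-state marker
        while i < n and cls[i] != _TARGET:
            i += 1
        if i == n:
            break
        # greedy extension under gap and allowance constraints
        n_opp = 0
        n_mis = 0
        k = i + 1
        while k < n:
            if positions[k] - positions[k - 1] > config.max_gap_bp:
                break
            c = cls[k]
            if c == _OPPOSITE:
                if n_opp + 1 > config.max_opposite:
                    break
                n_opp += 1
            elif c == _MISS:
                if n_mis + 1 > config.max_missing:
                    break
                n_mis += 1
            k += 1
        j = k - 1
        # trim the right flank back to the last target-state call
        jt = j
        while cls[jt] != _TARGET:
            if cls[jt] == _OPPOSITE:
                n_opp -= 1
            else:
                n_mis -= 1
            jt -= 1
        n_snps = jt - i + 1
        length = int(positions[jt] - positions[i])
        if n_snps >= config.min_snps and length >= config.min_length_bp:
            runs.append(RunSegment(
                sample_id=sample_id, population=population,
                chromosome=chromosome,
                start_bp=int(positions[i]), end_bp=int(positions[jt]),
                n_snps=n_snps, n_opposite=n_opp, n_missing=n_mis,
            ))
        # resume after the block; a budget-violating marker is never
        # target-state, so restarting at k loses nothing
        i = k
    return runs


RUN_COLUMNS = [
    "sample_id", "population", "chromosome", "start_bp", "end_bp",
    "n_snps", "n_opposite", "n_missing", "length_bp",
]


def runs_to_frame(runs: list[RunSegment]) -> pd.DataFrame:
    rows = [
        (r.sample_id, r.population, r.chromosome, r.start_bp, r.end_bp,
         r.n_snps, r.n_opposite, r.n_missing, r.length_bp)
        for r in runs
    ]
    df = pd.DataFrame(rows, columns=RUN_COLUMNS)
    for col in ("start_bp", "end_bp", "n_snps", "n_opposite", "n_missing",
                "length_bp"):
        df[col] = df[col].astype(np.int64)
    return df


def detect_runs_all(
    ds: GenotypeDataset,
    config: RunConfig,
    autosomes=SHEEP_AUTOSOMES,
) -> pd.DataFrame:
    """Detect runs for every individual on every configured autosome.

    Returns a DataFrame with columns ``RUN_COLUMNS`` in deterministic order
    (sample order of the dataset, chromosome map order, run start).
    """
    import warnings
    if ds.n_samples == 0 or ds.n_snps == 0:
        warnings.warn("empty dataset: no runs detected")
        return runs_to_frame([])
    auto = set(str(a) for a in autosomes)
    chrom_idx = [
        (chrom, ds.map.chromosome_indices(chrom))
        for chrom in ds.map.chromosomes
        if chrom in auto
    ]
    all_runs: list[RunSegment] = []
    sample_ids = ds.samples["sample_id"].to_numpy()
    pops = ds.samples["population"].to_numpy()
    positions = ds.map.positions
    for i in range(ds.n_samples):
        row = ds.genotypes[i]
        for chrom, idx in chrom_idx:
            all_runs.extend(detect_runs_one(
                row[idx], positions[idx], config,
                sample_id=str(sample_ids[i]), population=str(pops[i]),
                chromosome=str(chrom),
            ))
    return runs_to_frame(all_runs)
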