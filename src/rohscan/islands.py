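"""ROH islands: per-breed SNP incidence, top-percentile hotspots, overlaps.

A SNP's incidence in a breed is the fraction of the breed's individuals with
at least one ROH covering the SNP's position.  SNPs in the top percentile of
incidence (ties at the threshold included) are aggregated into maximal
map-consecutive blocks ("islands"); islands are then intersected with local
annotation intervals (QTL, genes) to report positional overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .data import AnnotationInterval, SnpMap


@dataclass(frozen=True)
class IslandRegion:
    """A contiguous run-incidence hotspot within one breed."""

    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    snp_ids: tuple[str, ...]

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class OverlapRecord:
    population: str
    island_chromosome: str
    island_start_bp: int
    island_end_bp: int
    annotation_name: str
    annotation_category: str
    overlap_bp: int


def snp_incidence(
    runs: pd.DataFrame,
    snp_map: SnpMap,
    samples: pd.DataFrame,
    population: str,
) -> pd.DataFrame:
    """Per-SNP ROH incidence within one breed.

    Returns a DataFrame aligned to the map with columns (chromosome,
    position, snp_id, count, fraction); ``count`` is the number of the
    breed's individuals with a run covering the SNP position (run start ≤
    position ≤ run end), ``fraction`` divides by the breed size.
    """
    members = samples[samples["population"] == population]
    if members.empty:
        raise ValueError(f"population {population!r} absent from samples")
    n_breed = len(members)
    member_ids = set(members["sample_id"])
    counts = np.zeros(len(snp_map), dtype=np.int64)
    pos_by_chrom = {
        chrom: (snp_map.chromosome_indices(chrom),)
        for chrom in snp_map.chromosomes
    }
    sub = runs[runs["sample_id"].isin(member_ids)]
    # per individual: boolean coverage, so overlapping runs count once
    for sid, per_sample in sub.groupby("sample_id", sort=False):
        covered = np.zeros(len(snp_map), dtype=bool)
        for chrom, per_chrom in per_sample.groupby("chromosome", sort=False):
            if str(chrom) not in pos_by_chrom:
                continue
            (idx,) = pos_by_chrom[str(chrom)]
            pos = snp_map.positions[idx]
            for start, end in zip(per_chrom["start_bp"], per_chrom["end_bp"]):
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="right")
                covered[idx[lo:hi]] = True
        counts += covered
    out = snp_map.df[["chromosome", "position", "snp_id"]].copy()
    out["count"] = counts
    out["fraction"] = counts / n_breed
    return out


def top_percentile_threshold(incidence: np.ndarray, pct: float = 1.0) -> float:
    """Incidence value of the ceil(n·pct/100)-th highest SNP.

    Selection is ``incidence >= threshold`` so ties at the threshold are all
    included (permutation-invariant).
    """
    if not (0 < pct < 100):
        raise ValueError("pct must be in (0, 100)")
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size == 0:
        raise ValueError("empty incidence vector")
    k = int(np.ceil(incidence.size * pct / 100.0))
    k = max(k, 1)
    return float(np.sort(incidence)[::-1][k - 1])


def aggregate_islands(
    selected: np.ndarray,
    snp_map: SnpMap,
    min_island_snps: int = 2,
    population: str = "",
    incidence: np.ndarray | None = None,
) -> list[IslandRegion]:
    """Aggregate map-consecutive selected SNPs into islands.

    ``selected`` is a boolean vector aligned to the map; blocks are maximal
    runs of consecutive selected SNPs on one chromosome (no bridging across
    unselected SNPs), and blocks shorter than ``min_island_snps`` are
    discarded.
    """
    selected = np.asarray(selected, dtype=bool)
    if len(selected) != len(snp_map):
        raise ValueError("selected flags not aligned to map")
    inc = np.asarray(incidence, dtype=float) if incidence is not None else None
    islands: list[IslandRegion] = []
    chroms = snp_map.df["chromosome"].to_numpy()
    pos = snp_map.positions
    ids = snp_map.snp_ids
    n = len(snp_map)
    i = 0
    while i < n:
        if not selected[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and selected[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_island_snps:
            peak = float(inc[i:j + 1].max()) if inc is not None else float("nan")
            islands.append(IslandRegion(
                population=population, chromosome=str(chroms[i]),
                start_bp=int(pos[i]), end_bp=int(pos[j]),
                n_snps=j - i + 1, peak_incidence=peak,
                snp_ids=tuple(ids[i:j + 1]),
            ))
        i = j + 1
    return islands


def call_islands(
    runs: pd.DataFrame,
    snp_map: SnpMap,
    samples: pd.DataFrame,
    pct: float = 1.0,
    min_island_snps: int = 2,
    per_breed: bool = True,
) -> tuple[list[IslandRegion], pd.DataFrame]:
    """Full island calling: incidence → top-percentile → aggregation.

    With ``per_breed=True`` (default) the percentile threshold is computed
    within each breed; otherwise a single dataset-wide incidence vector is
    used (population label ``"ALL"``).  Returns the islands and the long-
    format incidence table (one block per breed, with the threshold column).
    """
    if per_breed:
        groups = [str(p) for p in samples["population"].drop_duplicates()]
    else:
        groups = ["ALL"]
        samples = samples.assign(population="ALL")
        runs = runs.assign(population="ALL")
    islands: list[IslandRegion] = []
    tables = []
    for pop in groups:
        inc = snp_incidence(runs, snp_map, samples, pop)
        thr = top_percentile_threshold(inc["fraction"].to_numpy(), pct)
        sel = inc["fraction"].to_numpy() >= thr
        islands.extend(aggregate_islands(
            sel, snp_map, min_island_snps, population=pop,
            incidence=inc["fraction"].to_numpy(),
        ))
        inc = inc.assign(population=pop, threshold=thr)
        tables.append(inc)
    return islands, pd.concat(tables, ignore_index=True)


def overlap_annotations(
    islands: list[IslandRegion],
    annotations: list[AnnotationInterval],
) -> list[OverlapRecord]:
    """All (island, annotation) pairs with ≥1 bp positional intersection.

    Uses an interval tree per chromosome; overlap length follows the
    1-based inclusive convention (min(ends) − max(starts) + 1).
    """
    trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        # IntervalTree is half-open; store [start, end+1)
        trees.setdefault(str(ann.chromosome), IntervalTree()).addi(
            ann.start, ann.end + 1, ann)
    records: list[OverlapRecord] = []
    for isl in islands:
        tree = trees.get(str(isl.chromosome))
        if tree is None:
            continue
        hits = sorted(
            tree.overlap(isl.start_bp, isl.end_bp + 1),
            key=lambda iv: (iv.begin, iv.end, iv.data.name),
        )
        for iv in hits:
            ann = iv.data
            ov = min(isl.end_bp, ann.end) - max(isl.start_bp, ann.start) + 1
            if ov > 0:
                records.append(OverlapRecord(
                    population=isl.population,
                    island_chromosome=isl.chromosome,
                    island_start_bp=isl.start_bp,
                    island_end_bp=isl.end_bp,
                    annotation_name=ann.name,
                    annotation_category=ann.category,
                    overlap_bp=int(ov),
                ))
    return records


def islands_to_frame(islands: list[IslandRegion]) -> pd.DataFrame:
    rows = [
        (i.population, i.chromosome, i.start_bp, i.end_bp, i.n_snps,
         i.length_bp, i.peak_incidence, ";".join(i.snp_ids))
        for i in islands
    ]
    return pd.DataFrame(rows, columns=[
        "population", "chromosome", "start_bp", "end_bp", "n_snps",
        "length_bp", "peak_incidence", "snp_ids",
    ])


def overlaps_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    rows = [
        (r.population, r.island_chromosome, r.island_start_bp,
         r.island_end_bp, r.annotation_name, r.annotation_category,
         r.overlap_bp)
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "population", "chromosome", "island_start_bp", "island_end_bp",
        "annotation_name", "annotation_category", "overlap_bp",
    ])
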