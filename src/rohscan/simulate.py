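"""Synthetic genotype cohorts with known run structure and inbreeding.

Two generation modes share one marker scaffold:

* **planted** — background genotypes are drawn per SNP from Hardy–Weinberg
  proportions at the SNP's allele frequency; inside a planted autozygous
  tract both alleles are copied from one draw (homozygote by allele
  frequency), inside a planted heterozygous tract the call is forced to
  HET.  Genotyping error then flips each call to one of the other two
  called states with probability ε, and missingness is applied last.

* **pedigree** — a gene-drop: founder haplotypes are drawn per SNP by
  allele frequency and transmitted through meioses with Haldane (no
  interference) recombination, crossover count Poisson with mean equal to
  the chromosome length in Morgans (default 1 cM/Mb).  True autozygous
  intervals are the maximal regions where an individual's two haplotypes
  descend from the same founder haplotype copy, so classical expectations
  apply (full sibs E[F] = 1/4, half sibs 1/8, first cousins 1/16).

Both modes return the dataset together with a :class:`TruthSet` recording
the true intervals, enabling exact parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SnpMap


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale knobs for one synthetic cohort.

    Defaults give the desk-scale scaffold (5 chromosomes × 50 Mb × 1,000
    SNPs ≈ 50 kb spacing, the density regime of a 50k ovine array); allele
    frequencies uniform on [0.05, 0.5] so the background passes a 5% MAF
    filter.
    """

    n_chromosomes: int = 5
    chromosome_length_bp: int = 50_000_000
    n_snps_per_chromosome: int = 1_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    cm_per_mb: float = 1.0
    position_jitter: float = 0.3   # fraction of spacing; < 0.5 keeps order

    def __post_init__(self):
        for r in (self.missing_rate, self.error_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")

    @property
    def chromosome_length_morgans(self) -> float:
        return self.chromosome_length_bp / 1e6 * self.cm_per_mb / 100.0

    @property
    def genome_length_bp(self) -> int:
        return self.n_chromosomes * self.chromosome_length_bp


@dataclass(frozen=True)
class Tract:
    """A planted interval for one individual (1-based inclusive bp)."""

    sample_index: int
    chromosome: str
    start_bp: int
    end_bp: int
    kind: str   # "autozygous" | "heterozygous"

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("tract start > end")
        if self.kind not in ("autozygous", "heterozygous"):
            raise ValueError(f"unknown tract kind {self.kind!r}")


@dataclass
class TruthSet:
    """Known per-individual intervals: autozygous and heterozygous tracts."""

    intervals: pd.DataFrame   # sample_id, chromosome, start_bp, end_bp, kind
    genome_length_bp: int

    def autozygous_fraction(self) -> pd.Series:
        """Per-sample fraction of the genome inside true autozygous tracts."""
        auto = self.intervals[self.intervals["kind"] == "autozygous"]
        lengths = (auto["end_bp"] - auto["start_bp"] + 1).groupby(
            auto["sample_id"]).sum()
        return lengths / self.genome_length_bp

    def for_sample(self, sample_id: str, kind: str = "autozygous") -> pd.DataFrame:
        df = self.intervals
        return df[(df["sample_id"] == sample_id) & (df["kind"] == kind)]


# ---------------------------------------------------------------------------
# marker scaffold
# ---------------------------------------------------------------------------

def build_map(config: SimulationConfig, rng: np.random.Generator
              ) -> tuple[SnpMap, np.ndarray]:
    """Evenly spaced, jittered marker map plus per-SNP allele frequencies.

    Jitter below half the spacing keeps positions strictly increasing and
    every adjacent gap below twice the mean spacing, so the scaffold itself
    never triggers the 1 Mb gap rule at desk-scale densities.
    """
    records = []
    spacing = config.chromosome_length_bp / config.n_snps_per_chromosome
    for c in range(1, config.n_chromosomes + 1):
        base = (np.arange(config.n_snps_per_chromosome) + 0.5) * spacing
        jitter = rng.uniform(-config.position_jitter, config.position_jitter,
                             size=config.n_snps_per_chromosome) * spacing
        pos = np.maximum(1, (base + jitter).astype(np.int64))
        pos = np.unique(pos)
        while len(pos) < config.n_snps_per_chromosome:
            extra = rng.integers(1, config.chromosome_length_bp,
                                 size=config.n_snps_per_chromosome - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        for k, p in enumerate(pos):
            records.append((str(c), int(p), f"snp_{c}_{k}", "A", "G"))
    snp_map = SnpMap.from_records(records, sort=True)
    lo, hi = config.maf_range
    freq_b = rng.uniform(lo, hi, size=len(snp_map))   # frequency of allele B
    return snp_map, freq_b


def _apply_noise(
    genotypes: np.ndarray, config: SimulationConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Symmetric state-flip error with probability ε, then missingness."""
    g = genotypes.copy()
    if config.error_rate > 0:
        flip = rng.random(g.shape) < config.error_rate
        # move each flipped call to one of the two other called states
        offset = rng.integers(1, 3, size=g.shape)
        g = np.where(flip, (g + offset) % 3, g).astype(np.int8)
    if config.missing_rate > 0:
        g = np.where(rng.random(g.shape) < config.missing_rate,
                     np.int8(MISSING), g)
    return g


# ---------------------------------------------------------------------------
# planted mode
# ---------------------------------------------------------------------------

#: Flank-seal widths: opposite-state calls planted immediately outside each
#: tract, one more than the default detection allowance (1 het for ROH,
#: 3 hom for ROHet), so a run can never extend across a tract boundary and
#: planted boundaries are recoverable SNP-exactly.
AUTOZYGOUS_SEAL_SNPS = 2
HETEROZYGOUS_SEAL_SNPS = 4


def simulate_planted(
    config: SimulationConfig,
    tracts: list[Tract],
    n_individuals: int,
    population: str = "SIM",
    snp_map: SnpMap | None = None,
    freq_b: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str | None = None,
    seal_tracts: bool = True,
) -> tuple[GenotypeDataset, TruthSet]:
    """Hardy–Weinberg background with planted autozygous/heterozygous tracts.

    With ``seal_tracts`` (default) the background calls immediately flanking
    each tract are forced to the opposite state, in numbers exceeding the
    default allowances, so detected run boundaries coincide exactly with the
    first/last map SNP inside the tract instead of bleeding into background
    homozygosity."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if snp_map is None:
        snp_map, freq_b = build_map(config, rng)
    assert freq_b is not None

    for t in tracts:
        if not (0 <= t.sample_index < n_individuals):
            raise ValueError(f"tract sample_index {t.sample_index} out of range")
    # overlapping tracts for one individual are an error
    by_ind: dict[int, list[Tract]] = {}
    for t in tracts:
        by_ind.setdefault(t.sample_index, []).append(t)
    for idx, ts in by_ind.items():
        seen = sorted(((t.chromosome, t.start_bp, t.end_bp) for t in ts))
        for a, b in zip(seen, seen[1:]):
            if a[0] == b[0] and b[1] <= a[2]:
                raise ValueError(
                    f"overlapping planted tracts for individual {idx}")

    n_snps = len(snp_map)
    p_b = freq_b
    p_a = 1.0 - p_b
    # background genotypes from HW proportions at each SNP
    u = rng.random((n_individuals, n_snps))
    g = np.where(
        u < p_a ** 2, np.int8(HOM_A),
        np.where(u < p_a ** 2 + 2 * p_a * p_b, np.int8(HET), np.int8(HOM_B)),
    ).astype(np.int8)

    chroms = snp_map.df["chromosome"].to_numpy()
    pos = snp_map.positions
    prefix = sample_prefix if sample_prefix is not None else population
    sample_ids = [f"{prefix}_{i:03d}" for i in range(n_individuals)]
    truth_rows = []
    in_any_tract = np.zeros((n_individuals, n_snps), dtype=bool)
    tract_idx: list[np.ndarray] = []
    for t in tracts:
        on_chrom = chroms == t.chromosome
        idx = np.flatnonzero(
            on_chrom & (pos >= t.start_bp) & (pos <= t.end_bp))
        tract_idx.append(idx)
        in_any_tract[t.sample_index, idx] = True
        if t.kind == "autozygous":
            hom_draw = rng.random(len(idx)) < p_b[idx]
            g[t.sample_index, idx] = np.where(
                hom_draw, np.int8(HOM_B), np.int8(HOM_A))
        else:
            g[t.sample_index, idx] = HET
        truth_rows.append((
            sample_ids[t.sample_index], t.chromosome,
            t.start_bp, t.end_bp, t.kind,
        ))
    if seal_tracts:
        for t, idx in zip(tracts, tract_idx):
            if not len(idx):
                continue
            if t.kind == "autozygous":
                seal_state, n_seal = np.int8(HET), AUTOZYGOUS_SEAL_SNPS
            else:
                seal_state, n_seal = np.int8(HOM_A), HETEROZYGOUS_SEAL_SNPS
            chrom_idx = np.flatnonzero(chroms == t.chromosome)
            # seal SNPs sit outside every tract of this individual
            free = chrom_idx[~in_any_tract[t.sample_index, chrom_idx]]
            left = free[free < idx[0]][-n_seal:]
            right = free[free > idx[-1]][:n_seal]
            g[t.sample_index, left] = seal_state
            g[t.sample_index, right] = seal_state

    g = _apply_noise(g, config, rng)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "population": population,
    })
    ds = GenotypeDataset(map=snp_map, samples=samples, genotypes=g)
    truth = TruthSet(
        intervals=pd.DataFrame(truth_rows, columns=[
            "sample_id", "chromosome", "start_bp", "end_bp", "kind"]),
        genome_length_bp=config.genome_length_bp,
    )
    return ds, truth


def random_tracts(
    config: SimulationConfig,
    n_individuals: int,
    rng: np.random.Generator,
    n_long: int = 0,
    n_short: int = 0,
    n_het: int = 0,
    long_range_mb: tuple[float, float] = (16.0, 30.0),
    short_range_mb: tuple[float, float] = (1.0, 4.0),
    het_range_mb: tuple[float, float] = (1.0, 3.0),
    max_tries: int = 200,
    preplaced: list[Tract] | None = None,
) -> list[Tract]:
    """Random non-overlapping tracts per individual.

    ``n_long`` long (recent-inbreeding-like) and ``n_short`` short
    (historical-inbreeding-like) autozygous tracts plus ``n_het``
    heterozygous tracts, placed uniformly with rejection of overlaps.
    ``preplaced`` tracts (e.g., a shared hotspot) are respected when
    rejecting overlaps and returned as part of the result.
    """
    tracts: list[Tract] = list(preplaced) if preplaced else []
    L = config.chromosome_length_bp
    for ind in range(n_individuals):
        placed: dict[str, list[tuple[int, int]]] = {}
        for t in tracts:
            if t.sample_index == ind:
                placed.setdefault(t.chromosome, []).append(
                    (t.start_bp, t.end_bp))
        wanted = (
            [("autozygous", long_range_mb)] * n_long
            + [("autozygous", short_range_mb)] * n_short
            + [("heterozygous", het_range_mb)] * n_het
        )
        for kind, (lo_mb, hi_mb) in wanted:
            for _ in range(max_tries):
                length = int(rng.uniform(lo_mb, hi_mb) * 1e6)
                if length >= L:
                    continue
                chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
                start = int(rng.integers(1, L - length))
                end = start + length - 1
                ok = all(
                    e < start or s > end
                    for s, e in placed.get(chrom, [])
                )
                if ok:
                    placed.setdefault(chrom, []).append((start, end))
                    tracts.append(Tract(ind, chrom, start, end, kind))
                    break
    return tracts


# ---------------------------------------------------------------------------
# pedigree gene-drop mode
# ---------------------------------------------------------------------------

# A haplotype is, per chromosome, an ancestry mosaic: ``breaks`` are segment
# right edges (bp, last one = chromosome length) and ``ids`` the founder
# haplotype copy occupying each segment.
Mosaic = tuple[np.ndarray, np.ndarray]


def _founder_haplotype(hap_id: int, n_chrom: int, length: int) -> list[Mosaic]:
    return [
        (np.array([length], dtype=np.int64), np.array([hap_id], dtype=np.int64))
        for _ in range(n_chrom)
    ]


def _meiosis(
    hap_a: list[Mosaic], hap_b: list[Mosaic],
    config: SimulationConfig, rng: np.random.Generator,
) -> list[Mosaic]:
    """One gamete: Haldane crossovers between the parent's two haplotypes."""
    out: list[Mosaic] = []
    L = config.chromosome_length_bp
    morgans = config.chromosome_length_morgans
    for c in range(config.n_chromosomes):
        n_x = rng.poisson(morgans)
        cuts = np.sort(rng.integers(1, L, size=n_x)) if n_x else np.array([], dtype=np.int64)
        src = int(rng.integers(0, 2))
        sources = (hap_a[c], hap_b[c])
        breaks: list[int] = []
        ids: list[int] = []
        seg_start = 0
        for cut in list(cuts) + [L]:
            if cut <= seg_start:
                src ^= 1
                continue
            b, d = sources[src]
            lo = np.searchsorted(b, seg_start, side="right")
            hi = np.searchsorted(b, cut, side="left")
            for k in range(lo, hi + 1):
                end = min(int(b[k]), cut)
                if not breaks or ids[-1] != int(d[k]):
                    breaks.append(end)
                    ids.append(int(d[k]))
                else:
                    breaks[-1] = end
                if end == cut:
                    break
            seg_start = cut
            src ^= 1
        out.append((np.array(breaks, dtype=np.int64),
                    np.array(ids, dtype=np.int64)))
    return out


def _genotypes_from_haplotypes(
    hap_m: list[Mosaic], hap_p: list[Mosaic],
    snp_map: SnpMap, founder_alleles: np.ndarray,
) -> np.ndarray:
    """Genotype codes for one individual from its two ancestry mosaics.

    ``founder_alleles`` is (n_founder_haps, n_snps) of 0/1 alleles; the sum
    of the two transmitted alleles is directly the genotype code
    (0=HOM_A, 1=HET, 2=HOM_B).
    """
    n_snps = len(snp_map)
    g = np.empty(n_snps, dtype=np.int8)
    col = np.arange(n_snps)
    for c_i, chrom in enumerate(snp_map.chromosomes):
        idx = snp_map.chromosome_indices(chrom)
        pos = snp_map.positions[idx]
        alleles = []
        for hap in (hap_m, hap_p):
            breaks, ids = hap[c_i]
            seg = np.searchsorted(breaks, pos, side="left")
            hap_ids = ids[seg]
            alleles.append(founder_alleles[hap_ids, idx])
        g[idx] = (alleles[0] + alleles[1]).astype(np.int8)
    return g


def _autozygous_intervals(
    hap_m: list[Mosaic], hap_p: list[Mosaic], chromosomes: list[str],
) -> list[tuple[str, int, int]]:
    """Maximal regions where both mosaics carry the same founder copy."""
    out = []
    for c_i, chrom in enumerate(chromosomes):
        bm, im = hap_m[c_i]
        bp_, ip_ = hap_p[c_i]
        edges = np.union1d(bm, bp_)
        start = 1
        cur_start = None
        for edge in edges:
            id_m = im[np.searchsorted(bm, start, side="left")]
            id_p = ip_[np.searchsorted(bp_, start, side="left")]
            ibd = id_m == id_p
            if ibd and cur_start is None:
                cur_start = start
            if not ibd and cur_start is not None:
                out.append((chrom, cur_start, start - 1))
                cur_start = None
            start = int(edge) + 1
        if cur_start is not None:
            out.append((chrom, cur_start, int(edges[-1])))
    return out


#: Pedigree presets: (name, expected inbreeding coefficient of offspring).
PEDIGREE_PRESETS = {
    "outbred": 0.0,
    "full_sib": 0.25,
    "half_sib": 0.125,
    "first_cousin": 0.0625,
}


def simulate_pedigree(
    config: SimulationConfig,
    preset: str = "full_sib",
    n_offspring: int = 50,
    population: str = "PED",
    snp_map: SnpMap | None = None,
    freq_b: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str | None = None,
) -> tuple[GenotypeDataset, TruthSet]:
    """Gene-drop through a preset mating design; returns dataset + truth IBD.

    Presets: ``outbred`` (unrelated parents), ``full_sib`` (E[F]=0.25),
    ``half_sib`` (0.125), ``first_cousin`` (0.0625).  Each offspring is an
    independent mating of freshly dropped parents, so offspring are
    exchangeable replicates of the design.
    """
    if preset not in PEDIGREE_PRESETS:
        raise ValueError(
            f"unknown pedigree preset {preset!r}; "
            f"choose from {sorted(PEDIGREE_PRESETS)}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if snp_map is None:
        snp_map, freq_b = build_map(config, rng)
    assert freq_b is not None

    n_chrom = config.n_chromosomes
    L = config.chromosome_length_bp

    hap_counter = [0]

    def founder() -> tuple[list[Mosaic], list[Mosaic]]:
        h1 = _founder_haplotype(hap_counter[0], n_chrom, L)
        h2 = _founder_haplotype(hap_counter[0] + 1, n_chrom, L)
        hap_counter[0] += 2
        return h1, h2

    def child(pa, pb) -> tuple[list[Mosaic], list[Mosaic]]:
        return (_meiosis(pa[0], pa[1], config, rng),
                _meiosis(pb[0], pb[1], config, rng))

    offspring = []
    for _ in range(n_offspring):
        if preset == "outbred":
            p1, p2 = founder(), founder()
        elif preset == "full_sib":
            fa, fb = founder(), founder()
            p1, p2 = child(fa, fb), child(fa, fb)
        elif preset == "half_sib":
            sire, da, db = founder(), founder(), founder()
            p1, p2 = child(sire, da), child(sire, db)
        else:  # first_cousin
            ga, gb = founder(), founder()
            s1, s2 = child(ga, gb), child(ga, gb)
            ma, mb = founder(), founder()
            p1, p2 = child(s1, ma), child(s2, mb)
        offspring.append(child(p1, p2))

    n_haps = hap_counter[0]
    founder_alleles = (
        rng.random((n_haps, len(snp_map))) < freq_b[None, :]
    ).astype(np.int8)

    prefix = sample_prefix if sample_prefix is not None else population
    sample_ids = [f"{prefix}_{i:03d}" for i in range(n_offspring)]
    chromosomes = snp_map.chromosomes
    g = np.empty((n_offspring, len(snp_map)), dtype=np.int8)
    truth_rows = []
    for i, (hm, hp) in enumerate(offspring):
        g[i] = _genotypes_from_haplotypes(hm, hp, snp_map, founder_alleles)
        for chrom, s, e in _autozygous_intervals(hm, hp, chromosomes):
            truth_rows.append((sample_ids[i], chrom, s, e, "autozygous"))

    g = _apply_noise(g, config, rng)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": population})
    ds = GenotypeDataset(map=snp_map, samples=samples, genotypes=g)
    truth = TruthSet(
        intervals=pd.DataFrame(truth_rows, columns=[
            "sample_id", "chromosome", "start_bp", "end_bp", "kind"]),
        genome_length_bp=config.genome_length_bp,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# multi-breed cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """One breed's generator settings inside a multi-breed cohort.

    ``n_long`` / ``n_short`` autozygous and ``n_het`` heterozygous tracts
    are planted per individual, so breeds span inbreeding regimes from
    near-outbred to heavy recent inbreeding (several long tracts).
    ``hotspot`` is an optional shared autozygous region
    (chromosome, start_bp, end_bp, carrier_fraction) planted at the same
    position in a fixed fraction of the breed's individuals — the
    selection-signature analogue that island calling should recover.
    """

    label: str
    n_individuals: int
    n_long: int = 0
    n_short: int = 0
    n_het: int = 1
    hotspot: tuple[str, int, int, float] | None = None


MB = 1_000_000

#: Nine cohorts emulating a multi-breed conservation-program study
#: (cohort sizes 104, 100, 97, 99, 69, 50, 59, 104, 90).  Tract loads are
#: scaled to the desk genome (5 × 50 Mb) so per-breed F_ROH spans the
#: observed livestock range: near-outbred (~0.02) through heavy recent
#: inbreeding (~0.16), with the most inbred cohorts carrying the long
#: (>16 Mb) tracts.  Each breed carries one shared 2.5 Mb hotspot in 35%
#: of its individuals, mild enough to survive per-population HWE QC.
NINE_BREED_SPECS: tuple[CohortSpec, ...] = (
    CohortSpec("PMS", 104, n_long=0, n_short=5, n_het=2,
               hotspot=("1", 10 * MB, 12 * MB + MB // 2, 0.35)),
    CohortSpec("PZ", 100, n_long=0, n_short=2, n_het=1,
               hotspot=("2", 20 * MB, 22 * MB + MB // 2, 0.35)),
    CohortSpec("CMS", 97, n_long=1, n_short=3, n_het=1,
               hotspot=("3", 30 * MB, 32 * MB + MB // 2, 0.35)),
    CohortSpec("SW", 99, n_long=1, n_short=7, n_het=1,
               hotspot=("4", 40 * MB, 42 * MB + MB // 2, 0.35)),
    CohortSpec("UHR", 69, n_long=0, n_short=5, n_het=2,
               hotspot=("5", 5 * MB, 7 * MB + MB // 2, 0.35)),
    CohortSpec("MPOT", 50, n_long=0, n_short=6, n_het=1,
               hotspot=("1", 30 * MB, 32 * MB + MB // 2, 0.35)),
    CohortSpec("MPC", 59, n_long=1, n_short=6, n_het=1,
               hotspot=("2", 40 * MB, 42 * MB + MB // 2, 0.35)),
    CohortSpec("BH", 104, n_long=0, n_short=4, n_het=0,
               hotspot=("3", 10 * MB, 12 * MB + MB // 2, 0.35)),
    CohortSpec("WRZ", 90, n_long=1, n_short=1, n_het=1,
               hotspot=("4", 20 * MB, 22 * MB + MB // 2, 0.35)),
)


def generate_breed_cohort(
    config: SimulationConfig,
    specs: tuple[CohortSpec, ...] = NINE_BREED_SPECS,
) -> tuple[GenotypeDataset, TruthSet]:
    """Concatenate per-breed planted cohorts on one shared marker map."""
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate breed label in cohort specs")
    if len(specs) < 1:
        raise ValueError("at least one cohort spec required")
    rng = np.random.default_rng(config.seed)
    snp_map, freq_b = build_map(config, rng)
    parts = []
    truth_parts = []
    for spec in specs:
        preplaced: list[Tract] = []
        if spec.hotspot is not None:
            chrom, start, end, frac = spec.hotspot
            n_carriers = int(round(frac * spec.n_individuals))
            carriers = rng.choice(
                spec.n_individuals, size=n_carriers, replace=False)
            preplaced = [
                Tract(int(i), str(chrom), int(start), int(end), "autozygous")
                for i in sorted(carriers)
            ]
        tracts = random_tracts(
            config, spec.n_individuals, rng,
            n_long=spec.n_long, n_short=spec.n_short, n_het=spec.n_het,
            preplaced=preplaced,
        )
        ds, truth = simulate_planted(
            config, tracts, spec.n_individuals, population=spec.label,
            snp_map=snp_map, freq_b=freq_b, rng=rng,
        )
        parts.append(ds)
        truth_parts.append(truth.intervals)
    combined = GenotypeDataset(
        map=snp_map,
        samples=pd.concat([p.samples for p in parts], ignore_index=True),
        genotypes=np.vstack([p.genotypes for p in parts]),
    )
    truth = TruthSet(
        intervals=pd.concat(truth_parts, ignore_index=True),
        genome_length_bp=config.genome_length_bp,
    )
    return combined, truth
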