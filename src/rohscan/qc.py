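"""SNP-array quality control cascade.

The cascade mirrors standard medium-density array QC for multi-population
cohorts, in this fixed order:

1. sample call rate (retain iff call rate strictly exceeds the threshold),
2. chromosome exclusion (drop non-autosomal / unmapped markers),
3. per-SNP missingness (drop iff missing fraction strictly exceeds the cap),
4. pooled minor allele frequency (drop iff MAF strictly below the floor),
5. Hardy–Weinberg exact test per population (drop iff p < alpha in at least
   one population).

Every step appends a :class:`QcStep` record so removal counts reconcile
exactly from the raw input to the final marker set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SHEEP_AUTOSOMES


@dataclass(frozen=True)
class QcStep:
    name: str
    kind: str               # "sample" or "snp"
    n_removed: int
    n_remaining: int


@dataclass
class QcReport:
    """Ordered bookkeeping of the QC cascade."""

    steps: list[QcStep] = field(default_factory=list)

    def add(self, name: str, kind: str, n_removed: int, n_remaining: int) -> None:
        self.steps.append(QcStep(name, kind, n_removed, n_remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.kind, s.n_removed, s.n_remaining) for s in self.steps],
            columns=["step", "kind", "n_removed", "n_remaining"],
        )

    def check_consistency(self) -> bool:
        """Counts reconcile: previous remaining − removed == next remaining."""
        for kind in ("sample", "snp"):
            prev = None
            for s in self.steps:
                if s.kind != kind:
                    continue
                if prev is not None and prev - s.n_removed != s.n_remaining:
                    return False
                prev = s.n_remaining
        return True


class QcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_sample_call_rate(
    ds: GenotypeDataset, min_rate: float = 0.95,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Retain samples whose call rate strictly exceeds ``min_rate``."""
    if not (0 < min_rate <= 1):
        raise QcError("min_rate must be in (0, 1]")
    report = report if report is not None else QcReport()
    called = (ds.genotypes != MISSING).sum(axis=1)
    rate = called / ds.n_snps if ds.n_snps else np.ones(ds.n_samples)
    keep = rate > min_rate
    if not keep.any():
        raise QcError(
            "sample call-rate filter removed every sample; review min_rate"
        )
    out = ds.subset_samples(keep)
    report.add("sample_call_rate", "sample", int((~keep).sum()), out.n_samples)
    return out, report


def filter_chromosomes(
    ds: GenotypeDataset, autosomes=SHEEP_AUTOSOMES,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Drop markers outside the configured autosome set (Y, unmapped, ...)."""
    report = report if report is not None else QcReport()
    keep = ds.map.autosome_mask(autosomes)
    out = ds.subset_snps(keep)
    report.add("non_autosomal", "snp", int((~keep).sum()), out.n_snps)
    return out, report


def filter_snp_missingness(
    ds: GenotypeDataset, max_missing_fraction: float = 0.20,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Drop markers whose missing fraction strictly exceeds the cap."""
    if not (0 <= max_missing_fraction < 1):
        raise QcError("max_missing_fraction must be in [0, 1)")
    report = report if report is not None else QcReport()
    miss = (ds.genotypes == MISSING).mean(axis=0)
    keep = miss <= max_missing_fraction
    out = ds.subset_snps(keep)
    if out.n_snps == 0:
        warnings.warn("missingness filter removed every marker")
    report.add("snp_missingness", "snp", int((~keep).sum()), out.n_snps)
    return out, report


def minor_allele_frequency(ds: GenotypeDataset) -> np.ndarray:
    """Pooled per-marker MAF over non-missing genotypes (all populations)."""
    g = ds.genotypes
    n_aa = (g == HOM_A).sum(axis=0)
    n_ab = (g == HET).sum(axis=0)
    n_bb = (g == HOM_B).sum(axis=0)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n > 0, (2 * n_bb + n_ab) / (2 * n), 0.0)
    return np.minimum(freq_b, 1.0 - freq_b)


def filter_maf(
    ds: GenotypeDataset, min_maf: float = 0.05,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Drop markers with pooled MAF strictly below ``min_maf``."""
    report = report if report is not None else QcReport()
    maf = minor_allele_frequency(ds)
    keep = maf >= min_maf
    out = ds.subset_snps(keep)
    report.add("maf", "snp", int((~keep).sum()), out.n_snps)
    return out, report


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided exact Hardy–Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (no mid-p correction).  Returns p in (0, 1];
    a monomorphic marker has a single attainable configuration and p = 1.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise QcError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise QcError("all genotype counts are zero")
    rare = 2 * min(n_AA, n_BB) + n_AB           # minor allele count
    if rare == 0:
        return 1.0

    # Unnormalized conditional probabilities over heterozygote counts with
    # the same parity as the rare-allele count, via the standard two-sided
    # recurrence on het count.
    n_het_obs = n_AB
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward from the mode
    het = mid
    while het >= 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    # upward from the mode
    het = mid
    while het <= rare - 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / (
            (het + 2.0) * (het + 1.0))
        het += 2
    total = probs.sum()
    p_obs = probs[n_het_obs]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def genotype_counts_by_population(
    ds: GenotypeDataset,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-population (n_AA, n_AB, n_BB) count vectors over markers."""
    out = {}
    pops = ds.samples["population"].to_numpy()
    for pop in ds.populations:
        g = ds.genotypes[pops == pop]
        out[pop] = (
            (g == HOM_A).sum(axis=0),
            (g == HET).sum(axis=0),
            (g == HOM_B).sum(axis=0),
        )
    return out


def filter_hwe(
    ds: GenotypeDataset, alpha: float = 1e-5, per_population: bool = True,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Drop markers deviating from HWE (exact p < alpha) in any population.

    With ``per_population=False`` the test pools all individuals.
    Populations with fewer than 2 individuals are skipped with a warning.
    """
    report = report if report is not None else QcReport()
    remove = np.zeros(ds.n_snps, dtype=bool)
    if alpha > 0:
        if per_population:
            counts = genotype_counts_by_population(ds)
        else:
            g = ds.genotypes
            counts = {"__pooled__": (
                (g == HOM_A).sum(axis=0),
                (g == HET).sum(axis=0),
                (g == HOM_B).sum(axis=0),
            )}
        pop_sizes = ds.samples["population"].value_counts()
        for pop, (n_aa, n_ab, n_bb) in counts.items():
            if pop != "__pooled__" and pop_sizes.get(pop, 0) < 2:
                warnings.warn(
                    f"population {pop!r} has <2 individuals; skipped in HWE filter"
                )
                continue
            for j in range(ds.n_snps):
                if remove[j]:
                    continue
                n = int(n_aa[j] + n_ab[j] + n_bb[j])
                if n == 0:
                    continue
                if hwe_exact_pvalue(int(n_aa[j]), int(n_ab[j]), int(n_bb[j])) < alpha:
                    remove[j] = True
    out = ds.subset_snps(~remove)
    report.add("hwe", "snp", int(remove.sum()), out.n_snps)
    return out, report


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def apply_qc(
    ds: GenotypeDataset,
    min_call_rate: float = 0.95,
    autosomes=SHEEP_AUTOSOMES,
    max_missing_fraction: float = 0.20,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-5,
    hwe_per_population: bool = True,
) -> tuple[GenotypeDataset, QcReport]:
    """Run the full QC cascade in its fixed order and return the report."""
    report = QcReport()
    report.add("input_samples", "sample", 0, ds.n_samples)
    report.add("input_snps", "snp", 0, ds.n_snps)
    ds, report = filter_sample_call_rate(ds, min_call_rate, report)
    ds, report = filter_chromosomes(ds, autosomes, report)
    ds, report = filter_snp_missingness(ds, max_missing_fraction, report)
    ds, report = filter_maf(ds, min_maf, report)
    ds, report = filter_hwe(ds, hwe_alpha, hwe_per_population, report)
    return ds, report
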