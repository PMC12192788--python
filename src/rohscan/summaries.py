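"""Per-animal and per-breed run statistics, length classes, F_ROH, D_ROHet.

Length classes are cumulative "greater-than" sets: a run of length L belongs
to every class whose threshold t satisfies L > t.  This makes per-class
counts, length sums and genomic coefficients non-increasing along the
threshold ladder, matching how layered per-breed curves are read.

F_ROH is the genomic inbreeding coefficient of McQuillan-type estimators:
the summed length of an individual's ROH above a threshold divided by the
autosomal genome length covered by SNPs (per-chromosome span between the
first and last mapped marker).  D_ROHet is the analogous coverage fraction
for heterozygosity-rich runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeDataset, SHEEP_AUTOSOMES, SnpMap

MB = 1_000_000

#: ROH ladder: >1, >2, >4, >8, >16 Mb.
ROH_CLASSES: tuple[int, ...] = (1 * MB, 2 * MB, 4 * MB, 8 * MB, 16 * MB)
#: ROHet ladder: >0.5, >1, >1.5 Mb.
ROHET_CLASSES: tuple[int, ...] = (MB // 2, MB, 3 * MB // 2)


@dataclass(frozen=True)
class LengthClassScheme:
    """Strictly increasing thresholds (bp) defining cumulative >t classes."""

    thresholds_bp: tuple[int, ...]

    def __post_init__(self):
        t = self.thresholds_bp
        if len(t) == 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be non-empty, strictly increasing")

    def labels(self) -> list[str]:
        return [f">{t / MB:g}Mb" for t in self.thresholds_bp]

    def membership(self, length_bp) -> list[bool]:
        return [length_bp > t for t in self.thresholds_bp]


ROH_SCHEME = LengthClassScheme(ROH_CLASSES)
ROHET_SCHEME = LengthClassScheme(ROHET_CLASSES)


def covered_autosome_length(snp_map: SnpMap, autosomes=SHEEP_AUTOSOMES) -> int:
    """Sum over autosomes of (max SNP position − min SNP position)."""
    auto = set(str(a) for a in autosomes)
    total = 0
    found = False
    for chrom, grp in snp_map.df.groupby("chromosome", sort=False):
        if chrom not in auto:
            continue
        found = True
        pos = grp["position"].to_numpy()
        total += int(pos.max() - pos.min())
    if not found:
        raise ValueError("map contains no autosomal SNPs")
    return total


def classify_runs(runs: pd.DataFrame, scheme: LengthClassScheme
                  ) -> dict[str, pd.DataFrame]:
    """Cumulative class membership: run in class >t iff length_bp > t."""
    return {
        label: runs[runs["length_bp"] > t]
        for label, t in zip(scheme.labels(), scheme.thresholds_bp)
    }


def per_animal_summary(
    runs: pd.DataFrame,
    samples: pd.DataFrame,
    scheme: LengthClassScheme,
) -> pd.DataFrame:
    """Per (sample, class) run count and total length.

    ``samples`` supplies the full cohort (columns sample_id, population) so
    animals without any run contribute explicit zeros.
    """
    rows = []
    by_class = classify_runs(runs, scheme)
    for label in scheme.labels():
        sub = by_class[label]
        counts = sub.groupby("sample_id").size()
        sums = sub.groupby("sample_id")["length_bp"].sum()
        for _, s in samples.iterrows():
            sid = s["sample_id"]
            rows.append((
                sid, s["population"], label,
                int(counts.get(sid, 0)), int(sums.get(sid, 0)),
            ))
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "length_class",
                       "n_runs", "sum_length_bp"],
    )


def breed_summary(animal_summary: pd.DataFrame) -> pd.DataFrame:
    """Per (population, class) mean ± sample SD (n−1) of count and length sum.

    Zero-run animals are included in the means; a population with a single
    animal reports SD 0.
    """
    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    out = (
        animal_summary
        .groupby(["population", "length_class"], sort=False)
        .agg(
            n_animals=("sample_id", "size"),
            mean_n_runs=("n_runs", "mean"),
            sd_n_runs=("n_runs", _sd),
            mean_sum_length_bp=("sum_length_bp", "mean"),
            sd_sum_length_bp=("sum_length_bp", _sd),
        )
        .reset_index()
    )
    return out


def _coverage_fraction(
    runs: pd.DataFrame,
    samples: pd.DataFrame,
    snp_map: SnpMap,
    threshold_bp: int,
    autosomes=SHEEP_AUTOSOMES,
) -> pd.DataFrame:
    denom = covered_autosome_length(snp_map, autosomes)
    sub = runs[runs["length_bp"] > threshold_bp]
    sums = sub.groupby("sample_id")["length_bp"].sum()
    rows = []
    for _, s in samples.iterrows():
        sid = s["sample_id"]
        value = float(sums.get(sid, 0)) / denom
        rows.append((sid, s["population"], threshold_bp, value, denom))
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "threshold_bp",
                       "value", "denominator_bp"],
    )


def f_roh(
    roh_runs: pd.DataFrame,
    samples: pd.DataFrame,
    snp_map: SnpMap,
    threshold_bp: int,
    autosomes=SHEEP_AUTOSOMES,
) -> pd.DataFrame:
    """Per-sample F_ROH at one length threshold (cumulative >t class)."""
    return _coverage_fraction(roh_runs, samples, snp_map, threshold_bp, autosomes)


def d_rohet(
    rohet_runs: pd.DataFrame,
    samples: pd.DataFrame,
    snp_map: SnpMap,
    threshold_bp: int,
    autosomes=SHEEP_AUTOSOMES,
) -> pd.DataFrame:
    """Per-sample D_ROHet at one length threshold (cumulative >t class)."""
    return _coverage_fraction(rohet_runs, samples, snp_map, threshold_bp, autosomes)


def coefficient_table(
    runs: pd.DataFrame,
    samples: pd.DataFrame,
    snp_map: SnpMap,
    scheme: LengthClassScheme,
    autosomes=SHEEP_AUTOSOMES,
) -> pd.DataFrame:
    """Long-format coefficient table over the whole threshold ladder."""
    parts = [
        _coverage_fraction(runs, samples, snp_map, t, autosomes)
        for t in scheme.thresholds_bp
    ]
    return pd.concat(parts, ignore_index=True)
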