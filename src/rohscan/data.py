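"""Core containers: marker map, genotype matrix, annotation intervals.

Genotypes are stored as a dense ``int8`` matrix over four codes
(:data:`HOM_A`, :data:`HET`, :data:`HOM_B`, :data:`MISSING`), aligned column
by column to a :class:`SnpMap`.  All genomic coordinates inside the package
are 1-based inclusive (the PLINK MAP convention); BED import/export converts
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Genotype codes.  HOM_A/HOM_B refer to the marker's two alleles as recorded
# in the map; HET is heterozygous, MISSING an uncalled genotype.
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

GENOTYPE_CODES = frozenset({HOM_A, HET, HOM_B, MISSING})

#: Default autosome labels for sheep (Ovis aries, 26 autosomes).
SHEEP_AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 27))


def chromosome_sort_key(label: str) -> tuple[int, int | str]:
    """Natural sort key: numeric labels first in numeric order, others after."""
    s = str(label)
    if s.isdigit():
        return (0, int(s))
    return (1, s)


class SnpMap:
    """Ordered marker scaffold: chromosome, 1-based bp position, id, alleles.

    Wraps a DataFrame with columns ``chromosome`` (str), ``position`` (int),
    ``snp_id`` (str), ``allele_a``, ``allele_b``.  After canonical sorting,
    positions are strictly increasing within each chromosome and snp_ids are
    unique.
    """

    COLUMNS = ("chromosome", "position", "snp_id", "allele_a", "allele_b")

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True).copy()
        for col in ("chromosome", "snp_id", "allele_a", "allele_b"):
            if col not in df.columns:
                if col in ("allele_a", "allele_b"):
                    df[col] = "0"
                else:
                    raise ValueError(f"SnpMap requires column {col!r}")
            df[col] = df[col].astype(str)
        df["position"] = df["position"].astype(np.int64)
        self.df = df[list(self.COLUMNS)]
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.df["snp_id"].duplicated().any():
            dup = self.df["snp_id"][self.df["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in map")
        for chrom, grp in self.df.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- construction -----------------------------------------------------

    @staticmethod
    def canonical_order(df: pd.DataFrame) -> np.ndarray:
        """Permutation sorting markers by (chromosome natural order, position)."""
        keys = [chromosome_sort_key(c) for c in df["chromosome"]]
        order = sorted(
            range(len(df)),
            key=lambda i: (keys[i], int(df["position"].iloc[i])),
        )
        return np.asarray(order, dtype=np.int64)

    @classmethod
    def from_records(cls, records, sort: bool = True) -> "SnpMap":
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        if sort:
            order = cls.canonical_order(df)
            df = df.iloc[order]
        return cls(df)

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.df["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def autosome_mask(self, autosomes=SHEEP_AUTOSOMES) -> np.ndarray:
        auto = set(str(a) for a in autosomes)
        return self.df["chromosome"].isin(auto).to_numpy()

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.df["chromosome"] == str(chrom)).to_numpy())

    def subset(self, mask_or_idx) -> "SnpMap":
        sub = self.df.iloc[np.asarray(mask_or_idx).nonzero()[0]
                          if np.asarray(mask_or_idx).dtype == bool
                          else np.asarray(mask_or_idx)]
        return SnpMap(sub, validate=False)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, SnpMap) and self.df.equals(other.df)


@dataclass
class GenotypeDataset:
    """Individuals × markers genotype matrix with population labels.

    ``samples`` is a DataFrame with columns ``sample_id`` and ``population``;
    ``genotypes`` is an ``int8`` matrix of shape (n_samples, n_markers) over
    the four genotype codes, columns aligned to ``map``.
    """

    map: SnpMap
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n_s, n_m = self.genotypes.shape
        if n_s != len(self.samples):
            raise ValueError(
                f"genotype rows ({n_s}) != number of samples ({len(self.samples)})"
            )
        if n_m != len(self.map):
            raise ValueError(
                f"genotype columns ({n_m}) != number of markers ({len(self.map)})"
            )
        bad = ~np.isin(self.genotypes, (HOM_A, HET, HOM_B, MISSING))
        if bad.any():
            raise ValueError("genotype matrix contains codes outside "
                             "{HOM_A, HET, HOM_B, MISSING}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][
                self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if (self.samples["population"].astype(str).str.len() == 0).any():
            raise ValueError("empty population label")

    # -- shape ------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples["population"]:
            seen.setdefault(str(p), None)
        return list(seen)

    # -- subsetting -------------------------------------------------------

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            map=self.map.subset(keep),
            samples=self.samples.copy(),
            genotypes=self.genotypes[:, keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            map=self.map,
            samples=self.samples.iloc[keep],
            genotypes=self.genotypes[keep, :],
        )

    def restrict_autosomes(self, autosomes=SHEEP_AUTOSOMES) -> "GenotypeDataset":
        return self.subset_snps(self.map.autosome_mask(autosomes))

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.map.df.equals(other.map.df)
            and self.samples[["sample_id", "population"]].equals(
                other.samples[["sample_id", "population"]])
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class AnnotationInterval:
    """A named genomic interval (QTL or gene), 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    name: str
    category: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"interval {self.name!r}: start {self.start} > end {self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1
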